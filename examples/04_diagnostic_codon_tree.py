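"""Cluster family members by the codons under specificity-associated columns.

Rather than whole-gene phylogenies, the tree is built only from the
nucleotides encoding the diagnostic residues: codons under the planted
columns are extracted from each coding sequence, pairwise nucleotide
p-distances are computed, and a neighbor-joining tree is grown.  Members of
the same activity group should form tight clades.
"""

from corkosc import (
    FamilySpec,
    extract_codons,
    nj,
    p_distance,
    simulate_labeled_family,
    write_newick,
)

family = simulate_labeled_family(FamilySpec(seed=7))
columns = sorted(family.truth)
print(f"diagnostic columns: {columns}")

extract = extract_codons(family.protein_msa, family.cds, columns)
dm = p_distance(extract)
print(f"p-distance LUP_01:LUP_02 = {dm['LUP_01', 'LUP_02']:.3f} (same group)")
print(f"p-distance LUP_01:FRS_01 = {dm['LUP_01', 'FRS_01']:.3f} (different group)")

tree = nj(dm)
print("\nneighbor-joining tree (newick, truncated):")
print(" ", write_newick(tree)[:120], "...")

# clade purity: nearest neighbor of each taxon shares its activity label
pure = 0
for taxon in dm.ids:
    nearest = min((t for t in dm.ids if t != taxon), key=lambda t: dm[taxon, t])
    pure += taxon.split("_")[0] == nearest.split("_")[0]
print(f"\nnearest neighbor shares the activity label for {pure}/{len(dm.ids)} taxa")
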
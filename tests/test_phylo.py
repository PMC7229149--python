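import random

import numpy as np
import pytest
from skbio import DistanceMatrix
from skbio.tree import nj as skbio_nj

from corkosc import (
    FamilySpec,
    extract_codons,
    jc69_distance,
    nj,
    p_distance,
    read_newick,
    simulate_labeled_family,
    write_newick,
)
from corkosc.phylo import CodonExtract
from corkosc.seq import translate
from conftest import make_msa
from oracles import random_additive_tree


def tip_distances(tree):
    dm = tree.tip_tip_distances()
    return {frozenset((a, b)): dm[a, b] for a in dm.ids for b in dm.ids if a < b}


class TestExtractCodons:
    def test_unique_codon_residue(self):
        msa = make_msa(["M", "M"], ids=["a", "b"])
        ext = extract_codons(msa, {"a": "ATG", "b": "ATG"}, [1])
        assert ext.sequences == {"a": "ATG", "b": "ATG"}

    def test_gap_row_emits_gap_codon(self):
        msa = make_msa(["MK", "M-"], ids=["a", "b"])
        ext = extract_codons(msa, {"a": "ATGAAA", "b": "ATG"}, [2])
        assert ext.sequences["b"] == "---"
        assert ext.sequences["a"] == "AAA"

    def test_mismatch_names_taxon_and_residue(self):
        msa = make_msa(["MK"], ids=["a"])
        with pytest.raises(ValueError, match="a.*residue 2"):
            extract_codons(msa, {"a": "ATGGTT"}, [1])  # GTT = V, not K

    def test_extract_retranslates_to_planted_residues(self, default_family):
        fam = default_family
        columns = sorted(fam.truth)
        ext = extract_codons(fam.protein_msa, fam.cds, columns)
        for rec in fam.protein_msa.records:
            codons = ext.sequences[rec.id]
            for k, col in enumerate(columns):
                codon = codons[3 * k : 3 * k + 3]
                residue = rec.residues[col - 1]
                if residue == "-":
                    assert codon == "---"
                else:
                    assert translate(codon, 1) == residue


class TestPDistance:
    def test_identical_rows_are_zero(self):
        ext = CodonExtract(("a", "b"), (1,), {"a": "ATG", "b": "ATG"})
        assert p_distance(ext)["a", "b"] == 0.0

    def test_one_of_three_sites(self):
        ext = CodonExtract(("a", "b"), (1,), {"a": "ATG", "b": "ATA"})
        assert p_distance(ext)["a", "b"] == pytest.approx(1 / 3)

    def test_gap_sites_excluded(self):
        ext = CodonExtract(("a", "b"), (1, 2), {"a": "ATG---", "b": "ATACCC"})
        assert p_distance(ext)["a", "b"] == pytest.approx(1 / 3)

    def test_no_comparable_sites_rejected(self):
        ext = CodonExtract(("a", "b"), (1,), {"a": "---", "b": "ATG"})
        with pytest.raises(ValueError, match="comparable"):
            p_distance(ext)

    def test_matches_naive_recount(self):
        rng = random.Random(7)
        seqs = {
            t: "".join(rng.choice("ACGT-") for _ in range(30)) for t in ("a", "b", "c")
        }
        ext = CodonExtract(("a", "b", "c"), tuple(range(1, 11)), seqs)
        dm = p_distance(ext)
        for x, y in [("a", "b"), ("a", "c"), ("b", "c")]:
            comp = [
                (u, v)
                for u, v in zip(seqs[x], seqs[y])
                if u != "-" and v != "-"
            ]
            expected = sum(u != v for u, v in comp) / len(comp)
            assert dm[x, y] == pytest.approx(expected)

    def test_jc69_on_small_distance(self):
        ext = CodonExtract(("a", "b"), (1,), {"a": "ATG", "b": "ATA"})
        d = jc69_distance(ext)["a", "b"]
        assert d == pytest.approx(-0.75 * np.log(1 - 4 / 9))


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float), ids=list("ABC"))
        tree = nj(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == {"A": 1.0, "B": 1.0, "C": 3.0}

    def test_four_taxon_tree_recovered(self):
        # tree ((A:1,B:2):3,(C:4,D:5)) built by hand
        d = {
            ("A", "B"): 3.0,
            ("A", "C"): 8.0,
            ("A", "D"): 9.0,
            ("B", "C"): 9.0,
            ("B", "D"): 10.0,
            ("C", "D"): 9.0,
        }
        ids = list("ABCD")
        mat = np.zeros((4, 4))
        for (x, y), v in d.items():
            i, j = ids.index(x), ids.index(y)
            mat[i, j] = mat[j, i] = v
        tree = nj(DistanceMatrix(mat, ids=ids))
        got = tip_distances(tree)
        for (x, y), v in d.items():
            assert got[frozenset((x, y))] == pytest.approx(v, abs=1e-9)

    def test_additive_matrices_recovered_exactly(self):
        """Defining NJ guarantee: additive distances are reproduced."""
        rng = random.Random(31)
        for _ in range(15):
            n = rng.randrange(4, 11)
            taxa, dist = random_additive_tree(n, rng)
            mat = np.zeros((n, n))
            for i, x in enumerate(taxa):
                for j, y in enumerate(taxa):
                    if i != j:
                        mat[i, j] = dist[frozenset((x, y))]
            tree = nj(DistanceMatrix(mat, ids=taxa))
            got = tip_distances(tree)
            for pair, v in dist.items():
                assert got[pair] == pytest.approx(v, abs=1e-9)

    def test_tree_invariant_to_taxon_order(self):
        rng = random.Random(5)
        taxa, dist = random_additive_tree(6, rng)
        def build(order):
            mat = np.zeros((6, 6))
            for i, x in enumerate(order):
                for j, y in enumerate(order):
                    if i != j:
                        mat[i, j] = dist[frozenset((x, y))]
            return tip_distances(nj(DistanceMatrix(mat, ids=order)))
        shuffled = taxa[:]
        rng.shuffle(shuffled)
        a, b = build(taxa), build(shuffled)
        for pair in a:
            assert a[pair] == pytest.approx(b[pair], abs=1e-9)

    def test_asymmetric_matrix_rejected(self):
        mat = np.array([[0.0, 1.0, 2.0], [1.5, 0.0, 1.0], [2.0, 1.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            nj(mat)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj(DistanceMatrix(np.array([[0, 1], [1, 0]], float), ids=["a", "b"]))

    def test_agrees_with_skbio_on_random_additive_matrix(self):
        """Independent cross-check against scikit-bio's NJ."""
        rng = random.Random(17)
        taxa, dist = random_additive_tree(7, rng)
        mat = np.zeros((7, 7))
        for i, x in enumerate(taxa):
            for j, y in enumerate(taxa):
                if i != j:
                    mat[i, j] = dist[frozenset((x, y))]
        dm = DistanceMatrix(mat, ids=taxa)
        ours = tip_distances(nj(dm))
        theirs = tip_distances(skbio_nj(dm))
        for pair in ours:
            assert ours[pair] == pytest.approx(theirs[pair], abs=1e-9)

    def test_same_label_taxa_form_clades_on_synthetic_family(self):
        fam = simulate_labeled_family(FamilySpec(seed=3))
        ext = extract_codons(fam.protein_msa, fam.cds, sorted(fam.truth))
        tree = nj(p_distance(ext))
        # within-group tip distances should be smaller than between-group
        got = tip_distances(tree)
        within, between = [], []
        for pair, v in got.items():
            a, b = sorted(pair)
            (within if a.split("_")[0] == b.split("_")[0] else between).append(v)
        assert np.mean(within) < np.mean(between)


class TestNewick:
    def test_three_taxon_string(self):
        dm = DistanceMatrix(np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float), ids=list("ABC"))
        s = write_newick(nj(dm))
        assert set("ABC") <= set(s) and s.endswith(";")

    def test_round_trip_preserves_topology_and_lengths(self):
        rng = random.Random(23)
        for _ in range(5):
            taxa, dist = random_additive_tree(10, rng)
            mat = np.zeros((10, 10))
            for i, x in enumerate(taxa):
                for j, y in enumerate(taxa):
                    if i != j:
                        mat[i, j] = dist[frozenset((x, y))]
            tree = nj(DistanceMatrix(mat, ids=taxa))
            back = read_newick(write_newick(tree))
            a, b = tip_distances(tree), tip_distances(back)
            for pair in a:
                assert a[pair] == pytest.approx(b[pair], abs=1e-9)

    def test_empty_string_rejected(self):
        with pytest.raises(ValueError):
            read_newick("")
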
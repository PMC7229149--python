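# Methods

This note documents the models, rules and numerical choices behind corkosc,
what the synthetic-data generators do and do not emulate, and the known
limitations of each stage.

## Pairwise alignment and similarity percentages

`seq.global_align` computes an optimal global alignment with affine gap
costs: a gap of length L costs `gap_open + (L − 1) · gap_extend`, end gaps
included (true Needleman–Wunsch/Gotoh). Defaults are BLOSUM62 with gap open
10 and extend 0.5 — ClustalW-style parameters pinned for reproducibility,
since published "similarity percentages" for enzyme families rarely state
the program or matrix used. Two percentages are reported because the
literature is ambiguous about which is meant:

- **percent identity** — identical residue pairs / denominator;
- **percent similarity** — identical *or* positive-scoring (BLOSUM62 > 0)
  pairs / denominator.

The denominator defaults to the full alignment length including gap columns;
`denominator="shorter"` switches to the shorter input's length. Both choices
appear in the wild, and on diverged OSC pairs they differ by several
percentage points, so the choice is explicit rather than silent.
Coordinates are 1-based inclusive everywhere, matching residue-numbering
conventions like "Leu-491".

## Segregation scan

There is no standard formula for "a residue segregating with activity"; the
implemented rule is a deterministic modal-consensus threshold test chosen to
be auditable column by column. For a group *g* at column *c*, let *r* be the
group's most frequent non-gap residue. The column is called diagnostic for
*g* iff

1. overall gap fraction at *c* ≤ `max_gap` (default 0.3),
2. freq(*r* | in group) ≥ `tau_in` (default 0.9),
3. freq(*r* | out group) ≤ `tau_out` (default 0.2), and
4. *r* is not (tied for) the out-group's modal residue.

Gaps never count as a diagnostic residue (they reflect alignment, not
catalysis), and a tie for the in-group modal residue suppresses the call
(ambiguous consensus). Frequencies use the group size as denominator, so
gap-rich rows dilute consensus rather than being silently ignored. A
per-column mutual-information score (nats) between residue identity and
group membership is attached to every call for ranking; it is not used in
the calling rule. Raising `tau_in` or lowering `tau_out` can only remove
calls (monotonicity), which the tests verify.

The scan shares the known limitation of all column-wise association
methods: shared ancestry confounds the signal, since a residue fixed in one
clade may track phylogeny rather than catalysis. No phylogenetic correction
is applied; the diagnostic-codon tree (below) is the complementary view.

## ORF finding and the candidate filter

`mining.longest_orf` reports the longest ATG-initiated reading frame ending
at the first in-frame stop, searching both strands by default (similarity
search hits can land on either strand). The length **includes the stop
codon**; a frame that reaches the record end without a stop is still
reported, flagged `open_ended`, with a length truncated to whole codons.
Ties are broken toward the + strand, then the smallest start coordinate.
`filter_candidates` keeps a record iff its longest ORF is ≥ `min_orf_bp`
(default 1,500 — conservative, as plant OSC coding sequences exceed
2,000 bp) **and** the motif (default SDCTAE) occurs in the ORF's
translation. When aligned rows are supplied, a motif that exists in the
translation but is interrupted by gap characters in the aligned row is
reported as `MOTIF_GAPPED` rather than `MOTIF_ABSENT`. The ≥-boundary means
a record with exactly 1,500 bp is kept ("shorter than 1,500" is filtered).

## Diagnostic-codon phylogenetics

`phylo.extract_codons` pulls, for each taxon, the codon under each requested
protein-alignment column (after validating that the CDS translates exactly
to the ungapped aligned row; gap positions contribute `---`). Distances
default to the nucleotide **p-distance** over sites where neither taxon is
gapped — the minimal-assumption choice, exact on synthetic data; a
Jukes–Cantor correction (`jc69_distance`) is available where multiple hits
are a concern. A pair with no comparable sites is an error, not a zero.

`phylo.nj` is standard Saitou–Nei neighbor joining with the Q criterion.
Determinism is pinned: among tied pairs the one with the smallest index pair
in the current node order is joined. Negative branch-length estimates (a
known NJ artifact on non-additive input) are clamped to zero with a warning
and counted on the result (`tree.clamped_branches`). On additive matrices
NJ is exact, and the suite verifies path-length recovery to 1e-9 on random
trees of 4–10 taxa, plus agreement with scikit-bio's independent NJ
implementation. The requested column list is used exactly as given; callers
wanting a ±k window around positions of interest expand the list themselves.

## Expression standardization and specificity calls

`expression.zscores` standardizes each gene across samples with the sample
standard deviation (n−1). Rows whose variance is zero up to float rounding
(sd ≤ 1e-12 × mean magnitude) cannot be standardized and are dropped and
reported. TPM values are standardized directly by default; a log2(TPM+1)
pre-transform is available but off, matching the common practice of
z-scoring TPM for heatmaps. Tissue-level z is the mean of the tissue's
replicate-sample z values; means are banded **high** (z ≥ 0.9), **moderate**
(0.2 ≤ z ≤ 0.7), **low** (z ≤ −0.2), **intermediate** otherwise. The
moderate band is stated in some sources with inverted inequality signs
("0.7 ≤ z ≥ 0.2"); corkosc implements the only self-consistent reading,
0.2 ≤ z ≤ 0.7. A gene's enhanced tissue is the *unique* high tissue — zero
or several high tissues yield no call. Clustering of profiles is
average-linkage on Euclidean distances via SciPy (deterministic ordering).

## Redundancy nomination

Four evidence lines, all required by default, each individually relaxable:
same diagnostic-codon clade as the reference, all diagnostic residues
matching (mismatches rendered `C422S`-style), ORF ≥ 90% of the reference
CDS length, and the same enhanced tissue. The 90% threshold operationalizes
"missing a substantial portion of the coding sequence" — automation needs a
number; 660 bp missing from a ~2.3 kb OSC CDS (≈71%) is excluded with a wide
margin, while isoform-level length wobble is tolerated. The report is a
partition: every candidate is nominated or excluded with its failed
criteria, and adding criteria can only shrink the nomination set.
Nomination is evidence integration, not a claim of biological redundancy.

## qPCR and GC-FID quantification

Amplification efficiency comes from an OLS fit of Ct on log10 relative
template amount over a dilution series (≥ 3 points; 5-fold steps are
typical): E = 10^(−1/slope), with slope ≥ 0 rejected as an invalid curve.
Perfect doubling corresponds to slope −1/log10 2 ≈ −3.322. Relative
transcript abundance is the efficiency-corrected ratio
RTA = E_t^ΔCt_t / E_r^ΔCt_r. **The ΔCt sign convention is fixed as
control − sample** and the control is an explicit input (typically a pooled
cDNA mixture prepared at the bench); reversing the convention inverts fold
changes, which is why it is pinned in one place. GC-FID amounts are
area_i / area_IS × amount_IS / tissue_mass, in µg per mg dry tissue.

## Synthetic data: what is emulated, and what is not

All generators are seeded (`numpy.random.default_rng`) and byte-reproducible.
With all noise parameters at zero, every downstream estimator recovers the
planted truth exactly; the tests rely on this limit.

**Labeled families** (`simulate_labeled_family`). One random ancestor per
family; each sequence substitutes each site independently with probability
`background_divergence` (default 0.3) — a star topology, deliberately not a
tree-based evolution model. Planted diagnostic residues are written into
each target-group member, except for a fixed fraction
(`within_group_noise`, default 0.05) of members whose planted residue is
corrupted; the fraction is realized as an exact member count (halves round
up: 0.05 × 10 members → 1 corrupted member), so the within-group consensus
at a planted column is deterministic (0.9 for the defaults) rather than a
binomial draw. Two further constructional guarantees keep the planted truth
unambiguous: the ancestor never carries a diagnostic residue at its planted
column, and when backgrounds are stochastic no *non-target* group is allowed
to drift to near-fixation (modal fraction > 0.8) at a planted column —
otherwise the column would carry a second, accidental diagnostic signal and
"recovered exactly the planted set" would be ill-defined. Gaps are inserted
as whole columns in a random sequence subset, never at planted columns.
Codons are drawn uniformly over synonyms, which exercises codon extraction
without codon-usage realism; a consequence is that same-group taxa still
differ at synonymous positions of diagnostic codons, so diagnostic-codon
clades are tight but not zero-diameter.

**Transcripts** (`simulate_transcripts`). Each record is
flank + ORF + flank with the ORF length requested (multiple of 3, stop
included) and the SDCTAE motif encoded in-frame on request. Uniqueness of
the planted ORF is guaranteed combinatorially rather than by rejection
sampling: flanks contain no `A` (so no ATG, and no CAT — a reverse-strand
ATG — can form in them), junction patterns that could span flank and ORF
are excluded, and the ORF interior is sampled with no internal `ATG` and no
`CAT` trigram. Consequently each record contains exactly one start codon in
either strand and the longest-ORF truth is exact by construction. Tandem
duplicates copy the source record; inverted duplicates are its reverse
complement with coordinates mapped to the new strand; truncations remove
the 3' end of the ORF and everything downstream, leaving an open-ended
reading frame whose usable length is recorded. Not emulated: introns,
UTR realism, sequencing error, or multi-gene scaffolds as single records.

**Expression** (`simulate_expression`). Per-gene lognormal baselines
(median 20 TPM), a multiplicative enhancement (default 10×) in one planted
tissue, i.i.d. lognormal sample noise (scale 0.25 by default), six tissues
with 2–3 replicates. Genes with no enhancement and no noise are constant
rows and are expected to be dropped by standardization. Not emulated:
count-based sampling noise, library-size effects, correlated replicates, or
batch structure — so passing tests show the calling logic is correct, not
that the thresholds are robust on real RNA-seq.

**qPCR** (`simulate_qpcr`). Ct = Ct₀ − log10(amount)/log10(E) down a
dilution series (default 5-fold, 5 points), optional Gaussian replicate
noise in Ct units, and a control/sample Ct pair constructed so the
efficiency-corrected ratio equals a known `true_ratio`. With E = 2 and
2-fold dilution, Ct rises by exactly 1 per step.

## Problem sizes and determinism of the verification run

`scripts/acceptance.py` uses 20 family seeds for scan recovery, 100 label
permutations for the null, 50 random 2-kb records against the exhaustive
ORF oracle, 100 random protein pairs (length ≤ 8) against the exhaustive
alignment oracle, 50 random additive matrices (4–10 taxa) for NJ, 20
expression seeds for noisy recovery, and 10 end-to-end redundancy seeds —
sizes at which the exhaustive oracles are exact and the whole run completes
in well under a minute. All randomness derives from the `--seed` argument.

## Known limitations

- The segregation rule is association, not causation: it cannot separate
  activity-linked residues from clade-linked ones.
- p-distance saturates for deep divergences; JC69 helps only moderately.
- Specificity calls inherit the arbitrariness of fixed z bands; with few
  replicates per tissue, pure-noise genes can draw spurious calls.
- The redundancy rules formalize a judgment call; borderline candidates
  (e.g. one diagnostic mismatch but same clade and expression) are excluded
  by default and surface only when the relevant rule is relaxed.
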
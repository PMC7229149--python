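"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator is seeded and deterministic, and each returns its truth
alongside the data, so downstream estimators (segregation scan, ORF finder,
standard-curve fit, specificity caller, redundancy rules) can be tested
for exact recovery without any external download.

What is emulated
----------------
* ``simulate_labeled_family`` — groups of homologous proteins (with a
  consistent codon alignment) diverged i.i.d. per site from one random
  ancestor, with *planted* group-diagnostic residues at chosen columns, a
  controllable within-group corruption rate, and whole-column gaps placed
  only outside planted columns so the truth stays unambiguous.
* ``simulate_transcripts`` — transcript records with exactly one maximal
  open reading frame of requested length, optional in-frame SDCTAE motif,
  tandem/inverted duplicate copies, and 3'-truncated copies.  Uniqueness of
  the planted ORF is guaranteed by construction: flanks contain no ``A``
  (so no start codon can form outside the ORF on either strand) and the ORF
  interior is sampled with no internal ``ATG`` and no ``CAT`` trigram (so no
  reverse-strand start exists anywhere).
* ``simulate_expression`` — a genes x samples TPM matrix in which selected
  genes are enhanced in one tissue by a multiplicative effect, with
  lognormal sample noise.
* ``simulate_qpcr`` — a dilution-series Ct table with known amplification
  efficiencies plus a control/sample Ct table realizing a known abundance
  ratio.

None of this is a phylogenetic or read-level simulation: backgrounds are
star-shaped (no tree), codon usage is uniform over synonymous codons, and
expression noise is i.i.d. lognormal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .seq import Msa, SequenceRecord, reverse_complement, write_fasta

__all__ = [
    "FamilySpec",
    "SimulatedFamily",
    "TranscriptSpec",
    "SimulatedTranscripts",
    "ExpressionSpec",
    "SimulatedExpression",
    "QpcrSpec",
    "SimulatedQpcr",
    "simulate_labeled_family",
    "simulate_transcripts",
    "simulate_expression",
    "simulate_qpcr",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# aa -> synonymous codons, from the standard table
_CODONS: dict[str, list[str]] = {}
for codon, aa in standard_dna_table.forward_table.items():
    _CODONS.setdefault(aa, []).append(codon)
for aa in _CODONS:
    _CODONS[aa].sort()

_STOPS = set(standard_dna_table.stop_codons)

# fixed, construction-safe codons for SDCTAE (no ATG / CAT substring can
# arise inside or at the boundaries of this block)
_MOTIF_CODONS = {"S": "AGC", "D": "GAC", "C": "TGC", "T": "ACC", "A": "GCC", "E": "GAG"}
MOTIF = "SDCTAE"


def _check_fraction(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value}")


# --------------------------------------------------------------------------
# labeled protein/codon family
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FamilySpec:
    """Recipe for a labeled family with planted diagnostic residues."""

    groups: tuple[tuple[str, int], ...] = (("LUP", 10), ("AMY", 10), ("FRS", 10))
    length: int = 400
    planted: Mapping[int, tuple[str, str]] = field(
        default_factory=lambda: {
            50: ("LUP", "W"),
            120: ("LUP", "K"),
            200: ("AMY", "R"),
            280: ("AMY", "H"),
            350: ("FRS", "F"),
        }
    )
    background_divergence: float = 0.3
    within_group_noise: float = 0.05
    gap_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("at least one group required")
        for label, count in self.groups:
            if count < 1:
                raise ValueError(f"group {label!r} needs count >= 1")
        labels = {g for g, _ in self.groups}
        for col, (grp, res) in self.planted.items():
            if not 1 <= col <= self.length:
                raise ValueError(f"planted column {col} outside [1, {self.length}]")
            if grp not in labels:
                raise ValueError(f"planted group {grp!r} not among groups")
            if res not in AMINO_ACIDS:
                raise ValueError(f"invalid planted residue {res!r}")
        _check_fraction("background_divergence", self.background_divergence)
        _check_fraction("within_group_noise", self.within_group_noise)
        _check_fraction("gap_fraction", self.gap_fraction)


@dataclass(frozen=True)
class SimulatedFamily:
    """A protein alignment, its codon alignment, labels, and planted truth."""

    protein_msa: Msa
    codon_msa: Msa
    labels: Mapping[str, str]
    truth: Mapping[int, tuple[str, str]]  # column -> (group, residue)

    @property
    def cds(self) -> dict[str, str]:
        """Ungapped coding sequence per taxon (codon rows minus gap codons)."""
        return {r.id: r.residues.replace("-", "") for r in self.codon_msa.records}

    def planted_columns(self, group: str) -> list[int]:
        return sorted(c for c, (g, _) in self.truth.items() if g == group)

    def write(self, directory: str | Path) -> None:
        """Write protein/codon FASTA, a label table, and a JSON truth file."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_fasta(self.protein_msa.records, directory / "protein_msa.fasta")
        write_fasta(self.codon_msa.records, directory / "codon_msa.fasta")
        lines = [f"{i}\t{self.labels[i]}" for i in self.protein_msa.ids]
        (directory / "labels.tsv").write_text("\n".join(lines) + "\n")
        truth = {str(c): list(v) for c, v in self.truth.items()}
        (directory / "truth.json").write_text(json.dumps(truth, indent=1))


def _random_other(rng: np.random.Generator, exclude: str) -> str:
    choices = [a for a in AMINO_ACIDS if a != exclude]
    return choices[rng.integers(len(choices))]


def simulate_labeled_family(spec: FamilySpec) -> SimulatedFamily:
    """Generate a labeled protein + codon alignment with planted truth."""
    rng = np.random.default_rng(spec.seed)
    length = spec.length
    ids: list[str] = []
    labels: dict[str, str] = {}
    for grp, count in spec.groups:
        for k in range(count):
            sid = f"{grp}_{k + 1:02d}"
            ids.append(sid)
            labels[sid] = grp

    ancestor = [AMINO_ACIDS[i] for i in rng.integers(len(AMINO_ACIDS), size=length)]
    for col, (_, res) in spec.planted.items():
        while ancestor[col - 1] == res:
            ancestor[col - 1] = AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))]

    rows: dict[str, list[str]] = {}
    for sid in ids:
        seq = ancestor.copy()
        mask = rng.random(length) < spec.background_divergence
        for pos in np.flatnonzero(mask):
            seq[pos] = _random_other(rng, seq[pos])
        rows[sid] = seq
    # within_group_noise is the fraction of group members whose planted
    # residue is corrupted (rounded to a member count, halves up), so the
    # realized within-group consensus at a planted column is deterministic
    for col, (grp, res) in spec.planted.items():
        members = [sid for sid in ids if labels[sid] == grp]
        n_corrupt = int(np.floor(spec.within_group_noise * len(members) + 0.5))
        corrupted = set(rng.choice(len(members), size=n_corrupt, replace=False))
        for k, sid in enumerate(members):
            rows[sid][col - 1] = _random_other(rng, res) if k in corrupted else res
        # keep planted truth unambiguous: a non-target group must not drift
        # to near-fixation of any residue at a planted column, otherwise the
        # column would carry a second, accidental diagnostic signal
        if spec.background_divergence == 0:
            continue  # zero-divergence backgrounds are constant by definition
        for other, _count in spec.groups:
            if other == grp:
                continue
            others = [sid for sid in ids if labels[sid] == other]
            if len(others) < 2:
                continue
            while True:
                counts: dict[str, list[str]] = {}
                for sid in others:
                    counts.setdefault(rows[sid][col - 1], []).append(sid)
                modal_res, carriers = max(counts.items(), key=lambda kv: len(kv[1]))
                if len(carriers) / len(others) <= 0.8:
                    break
                sid = carriers[rng.integers(len(carriers))]
                replacement = _random_other(rng, modal_res)
                while replacement == res:
                    replacement = _random_other(rng, modal_res)
                rows[sid][col - 1] = replacement

    # whole-column gaps in a random subset of sequences, never at planted cols
    n_gap_cols = int(round(spec.gap_fraction * length))
    eligible = [c for c in range(1, length + 1) if c not in spec.planted]
    gap_cols = rng.choice(len(eligible), size=min(n_gap_cols, len(eligible)), replace=False)
    for gi in gap_cols:
        col = eligible[gi]
        gapped = rng.random(len(ids)) < 0.25
        for sid, g in zip(ids, gapped):
            if g:
                rows[sid][col - 1] = "-"

    prot_records = []
    codon_records = []
    for sid in ids:
        prot = "".join(rows[sid])
        codons = []
        for aa in rows[sid]:
            if aa == "-":
                codons.append("---")
            else:
                syn = _CODONS[aa]
                codons.append(syn[rng.integers(len(syn))])
        prot_records.append(SequenceRecord(sid, prot))
        codon_records.append(SequenceRecord(sid, "".join(codons)))
    return SimulatedFamily(
        protein_msa=Msa.from_records(prot_records),
        codon_msa=Msa.from_records(codon_records),
        labels=labels,
        truth=dict(spec.planted),
    )


# --------------------------------------------------------------------------
# transcript records with planted ORFs
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TranscriptSpec:
    """Recipe for transcript records with known ORFs, duplicates, truncations.

    ``duplications`` entries are ``(source_index, mode)`` with 0-based
    indices and mode ``'tandem'`` or ``'inverted'``; ``truncate`` entries are
    ``(record_index, nt_removed)`` and remove that many nucleotides from the
    3' end of the record's ORF together with everything downstream of it.
    """

    orf_lengths: tuple[int, ...] = (2160, 2160, 1497)
    include_motif: tuple[bool, ...] = (True, True, True)
    duplications: tuple[tuple[int, str], ...] = ()
    truncate: tuple[tuple[int, int], ...] = ()
    flank_length: int = 100
    seed: int = 0

    @property
    def n_records(self) -> int:
        return len(self.orf_lengths)

    def __post_init__(self) -> None:
        if len(self.include_motif) != self.n_records:
            raise ValueError("include_motif must match orf_lengths in length")
        for L in self.orf_lengths:
            if L < 6 or L % 3:
                raise ValueError(f"ORF length must be a multiple of 3 and >= 6, got {L}")
        for L, m in zip(self.orf_lengths, self.include_motif):
            if m and L < 3 * (2 + len(MOTIF)):
                raise ValueError("ORF too short to carry the motif")
        for src, mode in self.duplications:
            if not 0 <= src < self.n_records:
                raise ValueError(f"duplication source {src} out of range")
            if mode not in ("tandem", "inverted"):
                raise ValueError(f"unknown duplication mode {mode!r}")
        for idx, removed in self.truncate:
            if not 0 <= idx < self.n_records:
                raise ValueError(f"truncation index {idx} out of range")
            if removed <= 0 or removed >= self.orf_lengths[idx]:
                raise ValueError("truncation must remove part (not all) of the ORF")
        if self.flank_length < 0:
            raise ValueError("flank_length must be non-negative")


@dataclass(frozen=True)
class TranscriptTruth:
    record_id: str
    orf_start: int  # 1-based, forward-strand coordinates
    orf_end: int
    strand: str
    orf_length_bp: int
    has_motif: bool
    open_ended: bool
    truncated: bool


@dataclass(frozen=True)
class SimulatedTranscripts:
    records: tuple[SequenceRecord, ...]
    truth: tuple[TranscriptTruth, ...]
    scaffolds: tuple[tuple[str, tuple[tuple[str, str], ...]], ...]

    def truth_for(self, record_id: str) -> TranscriptTruth:
        for t in self.truth:
            if t.record_id == record_id:
                return t
        raise KeyError(record_id)

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_fasta(self.records, directory / "transcripts.fasta")
        payload = {
            "records": [asdict(t) for t in self.truth],
            "scaffolds": [
                {"scaffold": sid, "layout": [list(x) for x in layout]}
                for sid, layout in self.scaffolds
            ],
        }
        (directory / "truth.json").write_text(json.dumps(payload, indent=1))


def _sample_flank(rng: np.random.Generator, n: int, side: str) -> str:
    """A-free flank, so no start codon (ATG, or CAT on the reverse strand)
    can occur inside it.  A left flank must not end in C (else C + the ORF's
    "AT..." forms a junction CAT); a right flank must not start with TG
    (else the stop codon's final A forms a junction ATG)."""
    alphabet = "CGT"
    chars = [alphabet[i] for i in rng.integers(3, size=n)]
    if side == "left" and n:
        while chars[-1] == "C":
            chars[-1] = alphabet[rng.integers(3)]
    if side == "right" and n >= 2:
        while chars[0] == "T" and chars[1] == "G":
            chars[1] = alphabet[rng.integers(3)]
    return "".join(chars)


def _safe_orf(rng: np.random.Generator, orf_len: int, with_motif: bool) -> tuple[str, int | None]:
    """An ORF string ATG + body + TAA with no internal ATG and no CAT trigram.

    Returns the string and, when the motif is planted, the 0-based nt offset
    of its first codon within the ORF.
    """
    n_body = orf_len // 3 - 2
    codons = [c for c in standard_dna_table.forward_table if c not in ("ATG",)]
    for _ in range(1000):
        body: list[str] = []
        s = "ATG"
        ok = True
        for _ in range(n_body):
            for _try in range(100):
                cod = codons[rng.integers(len(codons))]
                cand = s + cod
                if "ATG" in cand[1:] or "CAT" in cand:
                    continue
                s = cand
                body.append(cod)
                break
            else:
                ok = False
                break
        if not ok:
            continue
        motif_off = None
        if with_motif:
            pos = int(rng.integers(0, n_body - len(MOTIF) + 1))
            for k, aa in enumerate(MOTIF):
                body[pos + k] = _MOTIF_CODONS[aa]
            motif_off = 3 * (1 + pos)
            s = "ATG" + "".join(body)
        full = s + "TAA"
        if "CAT" in full or "ATG" in full[1:]:
            continue
        return full, motif_off
    raise RuntimeError("could not construct a collision-free ORF")


def simulate_transcripts(spec: TranscriptSpec) -> SimulatedTranscripts:
    """Generate transcript records whose longest ORF is known by construction."""
    rng = np.random.default_rng(spec.seed)
    records: list[SequenceRecord] = []
    truths: list[TranscriptTruth] = []
    scaffolds: list[tuple[str, tuple[tuple[str, str], ...]]] = []
    truncate = dict(spec.truncate)

    base: dict[int, tuple[str, TranscriptTruth]] = {}
    for i, (orf_len, with_motif) in enumerate(zip(spec.orf_lengths, spec.include_motif)):
        rid = f"rec{i}"
        orf, motif_off = _safe_orf(rng, orf_len, with_motif)
        left = _sample_flank(rng, spec.flank_length, side="left")
        right = _sample_flank(rng, spec.flank_length, side="right")
        if i in truncate:
            removed = truncate[i]
            seq = left + orf[: orf_len - removed]
            # the reading frame now runs open-ended to the record end
            usable = len(seq) - spec.flank_length
            usable -= usable % 3
            motif_survives = with_motif and motif_off + 3 * len(MOTIF) <= usable
            t = TranscriptTruth(
                record_id=rid,
                orf_start=spec.flank_length + 1,
                orf_end=spec.flank_length + usable,
                strand="+",
                orf_length_bp=usable,
                has_motif=motif_survives,
                open_ended=True,
                truncated=True,
            )
        else:
            seq = left + orf + right
            t = TranscriptTruth(
                record_id=rid,
                orf_start=spec.flank_length + 1,
                orf_end=spec.flank_length + orf_len,
                strand="+",
                orf_length_bp=orf_len,
                has_motif=with_motif,
                open_ended=False,
                truncated=False,
            )
        base[i] = (seq, t)
        records.append(SequenceRecord(rid, seq))
        truths.append(t)

    for j, (src, mode) in enumerate(spec.duplications):
        seq, src_truth = base[src]
        dup_id = f"rec{src}_dup{j}"
        if mode == "tandem":
            dup_seq = seq
            dup_truth = TranscriptTruth(
                record_id=dup_id,
                orf_start=src_truth.orf_start,
                orf_end=src_truth.orf_end,
                strand="+",
                orf_length_bp=src_truth.orf_length_bp,
                has_motif=src_truth.has_motif,
                open_ended=src_truth.open_ended,
                truncated=src_truth.truncated,
            )
            layout = ((f"rec{src}", "+"), (dup_id, "+"))
        else:
            dup_seq = reverse_complement(seq)
            L = len(seq)
            dup_truth = TranscriptTruth(
                record_id=dup_id,
                orf_start=L - src_truth.orf_end + 1,
                orf_end=L - src_truth.orf_start + 1,
                strand="-",
                orf_length_bp=src_truth.orf_length_bp,
                has_motif=src_truth.has_motif,
                open_ended=src_truth.open_ended,
                truncated=src_truth.truncated,
            )
            layout = ((f"rec{src}", "+"), (dup_id, "-"))
        records.append(SequenceRecord(dup_id, dup_seq))
        truths.append(dup_truth)
        scaffolds.append((f"scaffold{j}", layout))

    return SimulatedTranscripts(
        records=tuple(records), truth=tuple(truths), scaffolds=tuple(scaffolds)
    )


# --------------------------------------------------------------------------
# expression matrix
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionSpec:
    """Recipe for a TPM matrix with one tissue-enhanced profile per gene.

    Defaults mirror a cork-oak style design: six tissues with phellem and
    phellogen better replicated, a 10x enhancement effect, and mild
    lognormal noise.
    """

    genes: tuple[str, ...] = tuple(f"gene{i:02d}" for i in range(12))
    tissues: tuple[tuple[str, int], ...] = (
        ("phellem", 3),
        ("phellogen", 3),
        ("inner_bark", 2),
        ("xylem", 2),
        ("leaf", 2),
        ("pollen", 2),
    )
    enhanced: Mapping[str, str | None] = field(
        default_factory=lambda: {f"gene{i:02d}": "phellem" if i < 6 else None for i in range(12)}
    )
    effect_size: float = 10.0
    noise_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.genes or not self.tissues:
            raise ValueError("genes and tissues must be non-empty")
        names = {t for t, _ in self.tissues}
        for gene, tissue in self.enhanced.items():
            if tissue is not None and tissue not in names:
                raise ValueError(f"enhanced tissue {tissue!r} for {gene!r} not in tissue list")
        if self.effect_size <= 0 or self.noise_sd < 0:
            raise ValueError("effect_size must be > 0 and noise_sd >= 0")


@dataclass(frozen=True)
class SimulatedExpression:
    tpm: pd.DataFrame
    tissue_map: Mapping[str, str]
    truth: Mapping[str, str | None]

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.tpm.to_csv(directory / "tpm.tsv", sep="\t")
        lines = [f"{s}\t{t}" for s, t in self.tissue_map.items()]
        (directory / "tissues.tsv").write_text("\n".join(lines) + "\n")
        (directory / "truth.json").write_text(json.dumps(dict(self.truth), indent=1))


def simulate_expression(spec: ExpressionSpec) -> SimulatedExpression:
    rng = np.random.default_rng(spec.seed)
    samples = []
    tissue_map = {}
    for tissue, reps in spec.tissues:
        if reps < 1:
            raise ValueError(f"tissue {tissue!r} needs at least 1 replicate")
        for r in range(reps):
            sid = f"{tissue}_{r + 1}"
            samples.append(sid)
            tissue_map[sid] = tissue
    data = np.empty((len(spec.genes), len(samples)))
    for gi, gene in enumerate(spec.genes):
        baseline = float(rng.lognormal(mean=np.log(20.0), sigma=0.5))
        enhanced = spec.enhanced.get(gene)
        for si, sid in enumerate(samples):
            mu = baseline * (spec.effect_size if tissue_map[sid] == enhanced else 1.0)
            noise = rng.lognormal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 1.0
            data[gi, si] = mu * noise
    tpm = pd.DataFrame(data, index=list(spec.genes), columns=samples)
    truth = {g: spec.enhanced.get(g) for g in spec.genes}
    return SimulatedExpression(tpm=tpm, tissue_map=tissue_map, truth=truth)


# --------------------------------------------------------------------------
# qPCR dilution series and sample Ct values
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class QpcrSpec:
    """Recipe for a standard curve + control/sample Ct pair with known ratio."""

    true_ratio: float = 4.0
    efficiency_target: float = 1.9
    efficiency_reference: float = 1.85
    dilution_factor: float = 5.0
    n_dilutions: int = 5
    replicate_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, e in (
            ("efficiency_target", self.efficiency_target),
            ("efficiency_reference", self.efficiency_reference),
        ):
            if not 1.0 < e <= 2.0:
                raise ValueError(f"{name} must be in (1, 2], got {e}")
        if self.true_ratio <= 0 or self.dilution_factor <= 0:
            raise ValueError("true_ratio and dilution_factor must be positive")
        if self.n_dilutions < 3:
            raise ValueError("need at least 3 dilution points")
        if self.replicate_sd < 0:
            raise ValueError("replicate_sd must be non-negative")


@dataclass(frozen=True)
class SimulatedQpcr:
    """Dilution series per gene, Ct table, and the generating truth."""

    dilution_series: Mapping[str, tuple[tuple[float, float], ...]]
    ct_table: Mapping[str, Mapping[str, float]]  # gene -> {control, sample}
    truth: Mapping[str, float]

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        lines = ["gene\tlog10_amount\tct"]
        for gene, pts in self.dilution_series.items():
            for x, ct in pts:
                lines.append(f"{gene}\t{x:.6g}\t{ct:.6g}")
        (directory / "dilution_series.tsv").write_text("\n".join(lines) + "\n")
        lines = ["gene\tcontrol_ct\tsample_ct"]
        for gene, cts in self.ct_table.items():
            lines.append(f"{gene}\t{cts['control']:.6g}\t{cts['sample']:.6g}")
        (directory / "ct_table.tsv").write_text("\n".join(lines) + "\n")
        (directory / "truth.json").write_text(json.dumps(dict(self.truth), indent=1))


def simulate_qpcr(spec: QpcrSpec) -> SimulatedQpcr:
    """Simulate Ct data: Ct = Ct0 - log10(amount) / log10(E), plus noise."""
    rng = np.random.default_rng(spec.seed)

    def noise() -> float:
        return float(rng.normal(0.0, spec.replicate_sd)) if spec.replicate_sd > 0 else 0.0

    series = {}
    ct0 = {"target": 20.0, "reference": 18.0}
    eff = {"target": spec.efficiency_target, "reference": spec.efficiency_reference}
    for gene in ("target", "reference"):
        pts = []
        for k in range(spec.n_dilutions):
            amount = spec.dilution_factor ** (-k)
            x = np.log10(amount)
            ct = ct0[gene] - x / np.log10(eff[gene]) + noise()
            pts.append((float(x), float(ct)))
        series[gene] = tuple(pts)

    dct_reference = 1.0
    dct_target = (
        np.log(spec.true_ratio) + dct_reference * np.log(eff["reference"])
    ) / np.log(eff["target"])
    ct_table = {
        "target": {"control": 20.0, "sample": 20.0 - float(dct_target) + noise()},
        "reference": {"control": 18.0, "sample": 18.0 - dct_reference + noise()},
    }
    truth = {
        "efficiency_target": eff["target"],
        "efficiency_reference": eff["reference"],
        "true_ratio": spec.true_ratio,
        "dct_target": float(dct_target),
        "dct_reference": dct_reference,
    }
    return SimulatedQpcr(dilution_series=series, ct_table=ct_table, truth=truth)
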
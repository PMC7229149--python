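"""Sequence I/O, translation, and pairwise global alignment.

Records are handled as plain ``(id, description, residues)`` triples wrapped
in :class:`SequenceRecord`; FASTA and Clustal parsing is delegated to
Biopython.  Pairwise protein comparison uses optimal global alignment with
affine gap costs (Needleman-Wunsch/Gotoh, via ``Bio.Align.PairwiseAligner``)
and reports both percent identity and percent similarity, since published
"similarity percentages" for enzyme families rarely state which of the two
was used.

Coordinates are 1-based inclusive throughout, matching the residue numbering
conventions of the enzymology literature (e.g. "Leu-491").
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import AlignIO, SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

__all__ = [
    "SequenceRecord",
    "Msa",
    "PairwiseAlignment",
    "read_fasta",
    "write_fasta",
    "translate",
    "reverse_complement",
    "global_align",
    "similarity_percentages",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_NT_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class SequenceRecord:
    """A named sequence; ``residues`` may contain ``-`` in aligned contexts."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record requires a non-empty id")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def ungapped(self) -> str:
        return self.residues.replace("-", "")


@dataclass(frozen=True)
class Msa:
    """An ordered multiple sequence alignment with equal-length gapped rows."""

    records: tuple[SequenceRecord, ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("alignment must contain at least one sequence")
        lengths = {len(r) for r in self.records}
        if len(lengths) != 1:
            raise ValueError(f"aligned rows have unequal lengths: {sorted(lengths)}")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicate sequence id in alignment: {dup!r}")
        if self.n_columns < 1:
            raise ValueError("alignment must have at least one column")

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def n_columns(self) -> int:
        return len(self.records[0])

    def __len__(self) -> int:
        return len(self.records)

    def row(self, seq_id: str) -> str:
        for r in self.records:
            if r.id == seq_id:
                return r.residues
        raise KeyError(seq_id)

    def column(self, col: int) -> str:
        """Residues of 1-based column ``col``, one character per sequence."""
        if not 1 <= col <= self.n_columns:
            raise IndexError(f"column {col} outside [1, {self.n_columns}]")
        return "".join(r.residues[col - 1] for r in self.records)

    @classmethod
    def from_records(cls, records: Iterable[SequenceRecord]) -> "Msa":
        return cls(tuple(records))

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Msa":
        return cls.from_records(read_fasta(path))

    @classmethod
    def from_clustal(cls, path: str | Path) -> "Msa":
        aln = AlignIO.read(str(path), "clustal")
        return cls.from_records(
            SequenceRecord(rec.id, str(rec.seq), rec.description) for rec in aln
        )


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read FASTA records; duplicate ids and empty files are rejected."""
    path = Path(path)
    records = [
        SequenceRecord(rec.id, str(rec.seq), rec.description)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id: {rec.id!r}")
        seen.add(rec.id)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [
        _BioRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def reverse_complement(nt: str) -> str:
    return nt.translate(_COMPLEMENT)[::-1]


def translate(nt: str, frame: int = 1) -> str:
    """Translate ``nt`` in the given frame (1, 2, 3, -1, -2, -3).

    Standard codon table; stops are rendered ``*``; codons containing N give
    ``X``; a trailing partial codon is dropped.  Negative frames read the
    reverse complement.
    """
    if frame not in (1, 2, 3, -1, -2, -3):
        raise ValueError(f"frame must be one of +-1, +-2, +-3, got {frame}")
    seq = nt.upper()
    bad = set(seq) - _NT_ALPHABET
    if bad:
        raise ValueError(f"invalid nucleotide characters: {sorted(bad)}")
    if frame < 0:
        seq = reverse_complement(seq)
    seq = seq[abs(frame) - 1 :]
    table = standard_dna_table.forward_table
    stops = set(standard_dna_table.stop_codons)
    out = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3]
        if "N" in codon:
            out.append("X")
        elif codon in stops:
            out.append("*")
        else:
            out.append(table[codon])
    return "".join(out)


@dataclass(frozen=True)
class PairwiseAlignment:
    """An optimal global alignment with identity/similarity percentages.

    ``percent_identity`` counts identical residue pairs; ``percent_similarity``
    additionally counts positive-scoring substitutions.  The denominator is
    the full alignment length (including gap columns) unless constructed with
    ``denominator='shorter'``.
    """

    aligned_a: str
    aligned_b: str
    score: float
    percent_identity: float
    percent_similarity: float
    matrix_name: str = field(default="BLOSUM62", compare=False)

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings differ in length")


def _load_matrix(matrix: str):
    return substitution_matrices.load(matrix)


def global_align(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    denominator: str = "alignment",
) -> PairwiseAlignment:
    """Optimal affine-gap global alignment of two ungapped protein sequences.

    A gap of length L costs ``gap_open + (L - 1) * gap_extend``; end gaps are
    penalized (true global alignment).  ``denominator`` selects whether the
    percentage denominators are the full alignment length (``'alignment'``,
    default) or the shorter input (``'shorter'``).
    """
    if not a or not b:
        raise ValueError("global_align requires non-empty sequences")
    if "-" in a or "-" in b:
        raise ValueError("inputs must be ungapped")
    if denominator not in ("alignment", "shorter"):
        raise ValueError("denominator must be 'alignment' or 'shorter'")
    mat = _load_matrix(matrix)
    alphabet = set(str(mat.alphabet))
    missing = (set(a) | set(b)) - alphabet
    if missing:
        raise ValueError(f"residues absent from {matrix}: {sorted(missing)}")

    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = mat
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    aln = aligner.align(a, b)[0]
    aligned_a, aligned_b = str(aln[0]), str(aln[1])

    n_cols = len(aligned_a)
    ident = sim = 0
    for x, y in zip(aligned_a, aligned_b):
        if x == "-" or y == "-":
            continue
        if x == y:
            ident += 1
            sim += 1
        elif mat[x, y] > 0:
            sim += 1
    denom = n_cols if denominator == "alignment" else min(len(a), len(b))
    return PairwiseAlignment(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=float(aln.score),
        percent_identity=100.0 * ident / denom,
        percent_similarity=100.0 * sim / denom,
        matrix_name=matrix,
    )


def similarity_percentages(
    cds: Mapping[str, str] | Sequence[SequenceRecord],
    mode: str = "similarity",
    **align_kwargs,
) -> dict[tuple[str, str], float]:
    """All pairwise percent similarities (or identities) of translated CDSs.

    ``cds`` maps ids to nucleotide coding sequences (or is a list of
    records); each is translated in frame 1, trailing stops stripped, and all
    pairs are globally aligned with the default scoring.
    """
    if not isinstance(cds, Mapping):
        cds = {r.id: r.residues for r in cds}
    proteins = {}
    for name, nt in cds.items():
        prot = translate(nt, 1).rstrip("*")
        if "*" in prot:
            raise ValueError(f"internal stop codon in CDS {name!r}")
        proteins[name] = prot
    attr = "percent_similarity" if mode == "similarity" else "percent_identity"
    out = {}
    for x, y in itertools.combinations(proteins, 2):
        aln = global_align(proteins[x], proteins[y], **align_kwargs)
        out[(x, y)] = getattr(aln, attr)
    return out
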
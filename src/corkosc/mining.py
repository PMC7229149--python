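"""Candidate-gene screening by longest-ORF length and motif integrity.

Genome mining for triterpene synthase genes typically starts from similarity
search hits and then discards fragments: hits whose longest open reading
frame is shorter than a cutoff (plant oxidosqualene cyclases are virtually
all > 2,000 bp, so 1,500 bp is a conservative floor) or whose catalytic
SDCTAE motif is absent or disrupted by alignment gaps.  This module
implements the ORF finder and that filter.

An ORF is an ATG-initiated codon run ending at the first in-frame stop; its
length in bp includes the stop codon.  A run that reaches the end of the
record without a stop is still reported, flagged ``open_ended``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .seq import SequenceRecord, reverse_complement, translate
from .segregation import motif_scan

__all__ = ["OrfAnnotation", "FilterDecision", "longest_orf", "filter_candidates"]

_STOPS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class OrfAnnotation:
    """Longest open reading frame of a record, in 1-based record coordinates.

    ``start``/``end`` are inclusive positions on the forward strand of the
    record regardless of ``strand``; ``frame`` is relative to the reading
    strand's own 5' end.
    """

    start: int
    end: int
    strand: str
    frame: int
    length_bp: int
    protein: str
    open_ended: bool = False

    def __post_init__(self) -> None:
        if self.length_bp and self.end - self.start + 1 != self.length_bp:
            raise ValueError("ORF coordinates inconsistent with length")

    @property
    def is_empty(self) -> bool:
        return self.length_bp == 0


_EMPTY_ORF = OrfAnnotation(start=0, end=-1, strand="+", frame=1, length_bp=0, protein="")


def _scan_strand(seq: str) -> list[tuple[int, int, int, bool]]:
    """All maximal ORFs on one strand: (0-based start, length, frame, open_ended).

    Maximal means ATG-initiated at the first start of its frame segment; for
    several in-frame ATGs sharing a stop only the earliest (longest) span is
    returned.
    """
    n = len(seq)
    orfs = []
    for offset in range(3):
        pending_start: int | None = None
        for i in range(offset, n - 2, 3):
            codon = seq[i : i + 3]
            if codon in _STOPS:
                if pending_start is not None:
                    orfs.append((pending_start, i + 3 - pending_start, offset + 1, False))
                    pending_start = None
            elif codon == "ATG" and pending_start is None:
                pending_start = i
        if pending_start is not None:
            usable = n - pending_start
            usable -= usable % 3
            orfs.append((pending_start, usable, offset + 1, True))
    return orfs


def longest_orf(nt: str, both_strands: bool = True) -> OrfAnnotation:
    """Longest ATG-initiated ORF of ``nt``; ties prefer + strand, then the
    smallest start coordinate.  Returns an empty annotation when no ATG
    exists on any searched frame."""
    seq = nt.upper()
    if len(seq) < 6:
        raise ValueError("record shorter than 6 nt cannot contain an ORF")
    candidates = []  # (length, strand_rank, start_on_record, frame, open_ended)
    for s0, length, frame, open_ended in _scan_strand(seq):
        candidates.append((length, 0, s0, frame, open_ended, "+"))
    if both_strands:
        rc = reverse_complement(seq)
        for s0, length, frame, open_ended in _scan_strand(rc):
            # map back to forward-strand record coordinates
            start_fwd = len(seq) - (s0 + length)
            candidates.append((length, 1, start_fwd, frame, open_ended, "-"))
    if not candidates:
        return _EMPTY_ORF
    length, _, start, frame, open_ended, strand = max(
        candidates, key=lambda c: (c[0], -c[1], -c[2])
    )
    if length == 0:
        return _EMPTY_ORF
    sub = seq[start : start + length]
    if strand == "-":
        sub = reverse_complement(sub)
    protein = translate(sub, 1)
    if protein.endswith("*"):
        protein = protein[:-1]
    return OrfAnnotation(
        start=start + 1,
        end=start + length,
        strand=strand,
        frame=frame,
        length_bp=length,
        protein=protein,
        open_ended=open_ended,
    )


@dataclass(frozen=True)
class FilterDecision:
    record_id: str
    kept: bool
    reasons: tuple[str, ...]
    orf: OrfAnnotation

    def __post_init__(self) -> None:
        if self.kept != (not self.reasons):
            raise ValueError("kept must be True exactly when no reasons are given")


def filter_candidates(
    records: Sequence[SequenceRecord],
    min_orf_bp: int = 1500,
    motif: str = "SDCTAE",
    both_strands: bool = True,
    aligned_rows: Mapping[str, str] | None = None,
) -> list[FilterDecision]:
    """Keep records whose longest ORF is >= ``min_orf_bp`` and whose
    translation carries the motif.

    When ``aligned_rows`` supplies aligned protein rows (alignment of the
    candidate translations), a motif present in the translation but broken
    by gap characters in the aligned row is discarded with reason
    ``MOTIF_GAPPED`` rather than ``MOTIF_ABSENT``.
    """
    if not records:
        raise ValueError("no candidate records supplied")
    decisions = []
    for rec in records:
        orf = longest_orf(rec.residues, both_strands=both_strands)
        reasons = []
        if orf.length_bp < min_orf_bp:
            reasons.append("ORF_TOO_SHORT")
        if motif:
            in_translation = bool(motif_scan(orf.protein, motif)) if orf.protein else False
            if not in_translation:
                reasons.append("MOTIF_ABSENT")
            elif aligned_rows is not None and rec.id in aligned_rows:
                if not motif_scan(aligned_rows[rec.id], motif):
                    reasons.append("MOTIF_GAPPED")
        decisions.append(
            FilterDecision(
                record_id=rec.id, kept=not reasons, reasons=tuple(reasons), orf=orf
            )
        )
    return decisions


def decisions_to_tsv(decisions: Iterable[FilterDecision], path: str | Path) -> None:
    lines = ["record_id\tkept\treasons\torf_start\torf_end\tstrand\torf_length_bp"]
    for d in decisions:
        lines.append(
            f"{d.record_id}\t{d.kept}\t{','.join(d.reasons) or '.'}"
            f"\t{d.orf.start}\t{d.orf.end}\t{d.orf.strand}\t{d.orf.length_bp}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
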
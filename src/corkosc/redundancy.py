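"""Rule-based nomination of putative redundant paralogs.

A candidate gene is nominated as potentially redundant with a characterized
reference enzyme when four lines of evidence agree: it falls in the same
diagnostic-codon clade, it encodes the reference's residues at every
specificity-associated alignment column, its open reading frame is
essentially full length (>= 90% of the reference CDS by default — a
candidate missing several hundred bp of coding sequence is excluded), and
its expression is enhanced in the same tissue.  Each criterion can be
relaxed individually to reproduce softer judgments.

Mismatches are reported in the conventional ``X<position>Y`` notation
(reference residue, alignment column, candidate residue), e.g. ``C422S``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "MatchRecord",
    "CandidateAnnotation",
    "NominationRules",
    "RedundancyReport",
    "diagnostic_match",
    "orf_complete",
    "nominate",
]


@dataclass(frozen=True)
class MatchRecord:
    column: int
    reference_residue: str
    candidate_residue: str
    match: bool

    @property
    def notation(self) -> str:
        """``C422S``-style substitution string; ``.`` for a match."""
        if self.match:
            return "."
        return f"{self.reference_residue}{self.column}{self.candidate_residue}"


def diagnostic_match(
    candidate_row: str,
    reference_row: str,
    columns: Sequence[int],
) -> list[MatchRecord]:
    """Compare candidate vs reference residues at 1-based alignment columns.

    Both rows must be on the same alignment coordinate system (equal
    length).  Gap characters never count as matching.
    """
    if len(candidate_row) != len(reference_row):
        raise ValueError("candidate and reference rows are not on a shared alignment")
    records = []
    for col in columns:
        if not 1 <= col <= len(reference_row):
            raise IndexError(f"column {col} beyond alignment of length {len(reference_row)}")
        ref = reference_row[col - 1]
        cand = candidate_row[col - 1]
        records.append(
            MatchRecord(
                column=col,
                reference_residue=ref,
                candidate_residue=cand,
                match=(ref == cand and ref != "-"),
            )
        )
    return records


def orf_complete(candidate_cds_bp: int, reference_cds_bp: int, min_frac: float = 0.9) -> bool:
    """Full-length test: candidate ORF within ``min_frac`` of the reference CDS."""
    if reference_cds_bp <= 0:
        raise ValueError("reference CDS length must be positive")
    return candidate_cds_bp >= min_frac * reference_cds_bp


@dataclass(frozen=True)
class CandidateAnnotation:
    """Evidence gathered for one candidate against one reference gene."""

    candidate_id: str
    reference_id: str
    clade: str
    reference_clade: str
    diagnostic_matches: tuple[MatchRecord, ...]
    orf_complete: bool
    enhanced_tissue: str | None
    reference_enhanced_tissue: str | None

    @property
    def all_diagnostic_match(self) -> bool:
        return all(m.match for m in self.diagnostic_matches)

    @property
    def mismatch_notation(self) -> list[str]:
        return [m.notation for m in self.diagnostic_matches if not m.match]


@dataclass(frozen=True)
class NominationRules:
    require_same_clade: bool = True
    require_all_diagnostic: bool = True
    require_full_orf: bool = True
    require_enhanced_tissue: bool = True


@dataclass(frozen=True)
class RedundancyReport:
    """Partition of candidates into nominations and exclusions."""

    nominations: tuple[tuple[str, str, str], ...]  # (candidate, reference, evidence)
    exclusions: tuple[tuple[str, tuple[str, ...]], ...]  # (candidate, failed criteria)

    def __post_init__(self) -> None:
        nominated = {c for c, _, _ in self.nominations}
        excluded = {c for c, _ in self.exclusions}
        if nominated & excluded:
            raise ValueError("a candidate cannot be both nominated and excluded")

    @property
    def nominated_ids(self) -> list[str]:
        return [c for c, _, _ in self.nominations]

    @property
    def excluded_ids(self) -> list[str]:
        return [c for c, _ in self.exclusions]

    def to_tsv(self, path: str | Path) -> None:
        lines = ["candidate\tstatus\treference_or_failed_criteria\tevidence"]
        for cand, ref, evidence in self.nominations:
            lines.append(f"{cand}\tnominated\t{ref}\t{evidence}")
        for cand, failed in self.exclusions:
            lines.append(f"{cand}\texcluded\t{','.join(failed)}\t.")
        Path(path).write_text("\n".join(lines) + "\n")


def nominate(
    annotations: Iterable[CandidateAnnotation],
    rules: NominationRules = NominationRules(),
) -> RedundancyReport:
    """Apply the redundancy rules to every candidate annotation."""
    annotations = list(annotations)
    nominations = []
    exclusions = []
    for ann in annotations:
        failed = []
        if rules.require_same_clade and ann.clade != ann.reference_clade:
            failed.append("different clade")
        if rules.require_all_diagnostic and not ann.all_diagnostic_match:
            failed.append(
                "diagnostic mismatch: " + ",".join(ann.mismatch_notation)
            )
        if rules.require_full_orf and not ann.orf_complete:
            failed.append("incomplete ORF")
        if rules.require_enhanced_tissue and (
            ann.enhanced_tissue is None
            or ann.enhanced_tissue != ann.reference_enhanced_tissue
        ):
            failed.append("expression not enhanced in the reference tissue")
        if failed:
            exclusions.append((ann.candidate_id, tuple(failed)))
        else:
            evidence = (
                f"clade={ann.clade};diagnostics={len(ann.diagnostic_matches)}/"
                f"{len(ann.diagnostic_matches)};orf=full;"
                f"enhanced={ann.enhanced_tissue}"
            )
            nominations.append((ann.candidate_id, ann.reference_id, evidence))
    return RedundancyReport(nominations=tuple(nominations), exclusions=tuple(exclusions))
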
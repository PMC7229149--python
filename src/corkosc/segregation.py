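"""Per-column segregation of residue identity with activity labels.

Given a protein alignment in which every sequence carries an activity label
(e.g. LUP for lupeol synthases, AMY for amyrin synthases, FRS for friedelin
synthases), these routines profile residue frequencies per column and call
*diagnostic positions*: columns whose modal residue is near-fixed inside one
activity group while rare outside it.  The calling rule is a deterministic
modal-consensus threshold rule — a column is called for a group when

* the overall gap fraction is at most ``max_gap``,
* the group's modal (non-gap) residue has within-group frequency >= ``tau_in``,
* that residue's frequency among all other sequences is <= ``tau_out``, and
* it differs from the out-group's modal residue.

A per-column mutual-information score between residue identity and group
membership is emitted alongside the calls for ranking purposes.  Gaps are
never treated as a diagnostic residue, and a tie for the modal residue
suppresses the call (ambiguous consensus).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from .seq import Msa

__all__ = [
    "LabeledMsa",
    "ColumnProfile",
    "SegregationCall",
    "SegregationReport",
    "column_profiles",
    "segregating_positions",
    "consensus_tracks",
    "column_mutual_information",
    "motif_scan",
    "motif_intact",
    "read_label_table",
]

GAP = "-"


@dataclass(frozen=True)
class LabeledMsa:
    """An alignment plus an activity label per sequence."""

    msa: Msa
    labels: Mapping[str, str]

    def __post_init__(self) -> None:
        missing = [i for i in self.msa.ids if i not in self.labels]
        if missing:
            raise ValueError(f"unlabeled sequences: {missing}")
        if len(set(self.labels[i] for i in self.msa.ids)) < 2:
            raise ValueError("need at least 2 distinct activity labels")

    def group_ids(self, group: str) -> list[str]:
        return [i for i in self.msa.ids if self.labels[i] == group]

    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for i in self.msa.ids:
            seen.setdefault(self.labels[i], None)
        return list(seen)


@dataclass(frozen=True)
class ColumnProfile:
    """Residue frequencies of one alignment column, split by group.

    Frequencies are per group over all group members, so each group's table
    (gap included under ``'-'``) sums to 1.
    """

    column: int
    group_frequencies: Mapping[str, Mapping[str, float]]
    gap_fraction: float


@dataclass(frozen=True)
class SegregationCall:
    column: int
    residue: str
    in_group_fraction: float
    out_group_fraction: float
    mutual_information: float = 0.0


@dataclass(frozen=True)
class SegregationReport:
    group: str
    tau_in: float
    tau_out: float
    max_gap: float
    calls: tuple[SegregationCall, ...]

    @property
    def columns(self) -> list[int]:
        return [c.column for c in self.calls]

    def to_tsv(self, path: str | Path) -> None:
        lines = ["column\tresidue\tin_group_fraction\tout_group_fraction\tmutual_information"]
        for c in self.calls:
            lines.append(
                f"{c.column}\t{c.residue}\t{c.in_group_fraction:.6g}"
                f"\t{c.out_group_fraction:.6g}\t{c.mutual_information:.6g}"
            )
        Path(path).write_text("\n".join(lines) + "\n")


def read_label_table(path: str | Path) -> dict[str, str]:
    """Read a two-column tab-delimited table of (sequence_id, activity_label)."""
    labels: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"malformed label line: {line!r}")
        labels[parts[0]] = parts[1]
    return labels


def column_profiles(lm: LabeledMsa) -> list[ColumnProfile]:
    """Per-column residue frequency tables, computed per activity group."""
    groups = lm.groups()
    members = {g: lm.group_ids(g) for g in groups}
    n_total = len(lm.msa)
    rows = {r.id: r.residues for r in lm.msa.records}
    profiles = []
    for col in range(1, lm.msa.n_columns + 1):
        freq: dict[str, dict[str, float]] = {}
        gaps = 0
        for g in groups:
            counts = Counter(rows[i][col - 1] for i in members[g])
            gaps += counts.get(GAP, 0)
            n = len(members[g])
            freq[g] = {res: c / n for res, c in counts.items()}
        profiles.append(
            ColumnProfile(column=col, group_frequencies=freq, gap_fraction=gaps / n_total)
        )
    return profiles


def _modal_residue(counts: Counter) -> tuple[str | None, int]:
    """Most frequent non-gap residue; ``None`` on a tie or when all-gap."""
    nongap = {res: c for res, c in counts.items() if res != GAP}
    if not nongap:
        return None, 0
    best = max(nongap.values())
    winners = [res for res, c in nongap.items() if c == best]
    if len(winners) > 1:
        return None, best
    return winners[0], best


def column_mutual_information(lm: LabeledMsa, group: str) -> list[float]:
    """Per-column MI (nats) between residue identity and group membership."""
    in_ids = set(lm.group_ids(group))
    rows = {r.id: r.residues for r in lm.msa.records}
    n = len(lm.msa)
    p_in = len(in_ids) / n
    out = []
    for col in range(lm.msa.n_columns):
        joint: Counter = Counter()
        for i in lm.msa.ids:
            joint[(rows[i][col], i in in_ids)] += 1
        marg_res: Counter = Counter()
        for (res, _), c in joint.items():
            marg_res[res] += c
        mi = 0.0
        for (res, member), c in joint.items():
            pxy = c / n
            px = marg_res[res] / n
            py = p_in if member else 1 - p_in
            mi += pxy * math.log(pxy / (px * py))
        out.append(max(mi, 0.0))
    return out


def segregating_positions(
    lm: LabeledMsa,
    group: str,
    tau_in: float = 0.9,
    tau_out: float = 0.2,
    max_gap: float = 0.3,
) -> SegregationReport:
    """Call columns whose residue identity segregates with ``group``."""
    in_ids = lm.group_ids(group)
    if group not in lm.groups():
        raise ValueError(f"label {group!r} not present in alignment")
    if len(in_ids) < 2:
        raise ValueError(f"group {group!r} has fewer than 2 members; consensus undefined")
    out_ids = [i for i in lm.msa.ids if lm.labels[i] != group]
    rows = {r.id: r.residues for r in lm.msa.records}
    n_total = len(lm.msa)
    mi = column_mutual_information(lm, group)

    calls = []
    for col in range(1, lm.msa.n_columns + 1):
        col_chars = [rows[i][col - 1] for i in lm.msa.ids]
        gap_fraction = col_chars.count(GAP) / n_total
        if gap_fraction > max_gap:
            continue
        in_counts = Counter(rows[i][col - 1] for i in in_ids)
        residue, best = _modal_residue(in_counts)
        if residue is None:
            continue
        in_frac = best / len(in_ids)
        if in_frac < tau_in:
            continue
        out_counts = Counter(rows[i][col - 1] for i in out_ids)
        out_frac = out_counts.get(residue, 0) / len(out_ids)
        if out_frac > tau_out:
            continue
        out_modal, out_best = _modal_residue(out_counts)
        # tie in the out-group modal residue: treat the diagnostic residue as
        # not distinct if it shares the maximal out-group count
        nongap_out = {r: c for r, c in out_counts.items() if r != GAP}
        if nongap_out and out_counts.get(residue, 0) == max(nongap_out.values()):
            continue
        if out_modal is not None and out_modal == residue:
            continue
        calls.append(
            SegregationCall(
                column=col,
                residue=residue,
                in_group_fraction=in_frac,
                out_group_fraction=out_frac,
                mutual_information=mi[col - 1],
            )
        )
    return SegregationReport(
        group=group, tau_in=tau_in, tau_out=tau_out, max_gap=max_gap, calls=tuple(calls)
    )


def consensus_tracks(lm: LabeledMsa, group: str) -> list[tuple[float, float]]:
    """Per-column (within-group, out-group) modal-residue consensus fractions.

    Mirrors the consensus tracks drawn above activity-labeled family
    alignments: 1.0 where a group is fixed for one residue, lower where the
    column is variable; gaps never count toward consensus.
    """
    in_ids = lm.group_ids(group)
    out_ids = [i for i in lm.msa.ids if lm.labels[i] != group]
    if not in_ids or not out_ids:
        raise ValueError("both the group and its complement must be non-empty")
    rows = {r.id: r.residues for r in lm.msa.records}
    track = []
    for col in range(lm.msa.n_columns):
        in_counts = Counter(rows[i][col] for i in in_ids)
        out_counts = Counter(rows[i][col] for i in out_ids)
        _, in_best = _modal_residue(in_counts)
        _, out_best = _modal_residue(out_counts)
        track.append((in_best / len(in_ids), out_best / len(out_ids)))
    return track


def motif_scan(sequence: str, motif: str = "SDCTAE") -> list[int]:
    """1-based start positions of exact occurrences of ``motif``.

    On an aligned row the positions are alignment coordinates; a gap inside
    the motif span means no hit at that offset.
    """
    if not motif or GAP in motif:
        raise ValueError("motif must be non-empty and ungapped")
    hits = []
    start = 0
    while True:
        idx = sequence.find(motif, start)
        if idx == -1:
            return hits
        hits.append(idx + 1)
        start = idx + 1


def motif_intact(lm: LabeledMsa | Msa, motif: str = "SDCTAE") -> dict[str, bool]:
    """Whether each aligned row carries the motif contiguously and ungapped."""
    msa = lm.msa if isinstance(lm, LabeledMsa) else lm
    return {r.id: bool(motif_scan(r.residues, motif)) for r in msa.records}
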
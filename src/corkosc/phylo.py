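"""Diagnostic-codon phylogenetics: codon extraction, distances, neighbor joining.

To cluster family members by the residues that determine product specificity
rather than by whole-gene similarity, the codons underlying selected protein
alignment columns are extracted from each taxon's coding sequence and
concatenated; pairwise distances over those nucleotides then feed a
neighbor-joining tree.

Distances default to the nucleotide p-distance (proportion of differing
sites among positions where neither taxon is gapped); a Jukes-Cantor
correction is available.  Neighbor joining is the standard Saitou-Nei
agglomeration with the Q criterion, deterministic tie-breaking by the
smallest taxon-index pair, and negative branch-length estimates clamped to
zero (recorded on the result).  On additive distance matrices the method is
exact: tree path lengths reproduce the input distances.

Trees are :class:`skbio.TreeNode` objects; newick I/O goes through skbio.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .seq import Msa, translate

__all__ = [
    "CodonExtract",
    "extract_codons",
    "p_distance",
    "jc69_distance",
    "nj",
    "write_newick",
    "read_newick",
]

GAP_CODON = "---"


@dataclass(frozen=True)
class CodonExtract:
    """Concatenated codons under selected protein-alignment columns.

    ``sequences[t]`` has ``3 * len(columns)`` characters for every taxon
    ``t``; a taxon gapped at a requested column contributes ``---``.
    """

    taxa: tuple[str, ...]
    columns: tuple[int, ...]
    sequences: Mapping[str, str]

    def __post_init__(self) -> None:
        want = 3 * len(self.columns)
        for t in self.taxa:
            if len(self.sequences[t]) != want:
                raise ValueError(f"taxon {t!r}: expected {want} nt")


def extract_codons(
    protein_msa: Msa,
    cds: Mapping[str, str],
    columns: Sequence[int],
) -> CodonExtract:
    """Pull the codons encoding the residues at 1-based alignment ``columns``.

    Every coding sequence must translate (frame 1, trailing stop allowed) to
    its ungapped aligned row; a mismatch raises with the taxon and the first
    discordant residue.
    """
    if not columns:
        raise ValueError("no columns requested")
    for col in columns:
        if not 1 <= col <= protein_msa.n_columns:
            raise IndexError(f"column {col} outside [1, {protein_msa.n_columns}]")
    sequences = {}
    for rec in protein_msa.records:
        if rec.id not in cds:
            raise KeyError(f"no coding sequence for taxon {rec.id!r}")
        nt = cds[rec.id].upper()
        prot = translate(nt, 1).rstrip("*")
        ungapped = rec.ungapped
        if prot != ungapped:
            for k, (a, b) in enumerate(zip(prot, ungapped)):
                if a != b:
                    raise ValueError(
                        f"CDS/protein mismatch for {rec.id!r} at residue {k + 1}: "
                        f"CDS encodes {a!r}, alignment has {b!r}"
                    )
            raise ValueError(
                f"CDS/protein length mismatch for {rec.id!r}: "
                f"{len(prot)} vs {len(ungapped)} residues"
            )
        # residue index (0-based, ungapped) for each alignment column
        parts = []
        for col in columns:
            row = rec.residues
            if row[col - 1] == "-":
                parts.append(GAP_CODON)
            else:
                res_idx = col - 1 - row[: col - 1].count("-")
                parts.append(nt[3 * res_idx : 3 * res_idx + 3])
        sequences[rec.id] = "".join(parts)
    return CodonExtract(
        taxa=tuple(protein_msa.ids), columns=tuple(columns), sequences=sequences
    )


def _pairwise_p(a: str, b: str) -> float:
    comparable = diffs = 0
    for x, y in zip(a, b):
        if x == "-" or y == "-":
            continue
        comparable += 1
        if x != y:
            diffs += 1
    if comparable == 0:
        raise ValueError("no comparable (non-gap) sites between a pair of taxa")
    return diffs / comparable


def p_distance(extract: CodonExtract) -> DistanceMatrix:
    """Nucleotide p-distance over the extracted codons."""
    taxa = extract.taxa
    if len(taxa) < 2:
        raise ValueError("need at least 2 taxa")
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _pairwise_p(
                extract.sequences[taxa[i]], extract.sequences[taxa[j]]
            )
    return DistanceMatrix(d, ids=list(taxa))


def jc69_distance(extract: CodonExtract) -> DistanceMatrix:
    """Jukes-Cantor corrected distance, d = -3/4 ln(1 - 4p/3)."""
    pd = p_distance(extract)
    d = pd.data.copy()
    sat = d >= 0.75
    if sat.any():
        raise ValueError("p-distance >= 0.75 cannot be JC69-corrected")
    with np.errstate(divide="ignore"):
        corrected = -0.75 * np.log1p(-4.0 * d / 3.0)
    np.fill_diagonal(corrected, 0.0)
    return DistanceMatrix(corrected, ids=list(pd.ids))


def nj(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining.

    Deterministic: when several pairs minimize the Q criterion the pair with
    the smallest (i, j) indices in the current node order is joined.
    Negative branch-length estimates are clamped to zero with a warning; the
    number of clamped branches is stored on the returned tree as
    ``tree.clamped_branches``.
    """
    if isinstance(dm, np.ndarray):
        if not np.allclose(dm, dm.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        dm = DistanceMatrix(dm)
    taxa = list(dm.ids)
    if len(taxa) < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    d = dm.data.astype(float).copy()
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")

    nodes: list[TreeNode] = [TreeNode(name=t) for t in taxa]
    clamped = 0

    def _clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += 1
            return 0.0
        return x

    while len(nodes) > 2:
        n = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * d[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-15:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (n - 2))
        lj = d[i, j] - li
        parent = TreeNode()
        a, b = nodes[i], nodes[j]
        a.length = _clamp(li)
        b.length = _clamp(lj)
        parent.extend([a, b])
        new_d = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        d2 = np.zeros((len(keep) + 1, len(keep) + 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = new_d[keep]
        d = d2
        nodes = [nodes[k] for k in keep] + [parent]

    # two nodes remain; at least one is internal (initial n >= 3).  Use the
    # internal one as the (trifurcating, unrooted) root and hang the other
    # off it with the remaining distance.
    a, b = nodes
    if a.is_tip():
        a, b = b, a
    b.length = _clamp(d[0, 1])
    a.append(b)
    root = a
    root.length = None
    if clamped:
        warnings.warn(f"{clamped} negative NJ branch estimate(s) clamped to zero")
    root.clamped_branches = clamped
    return root


def write_newick(tree: TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def read_newick(s: str) -> TreeNode:
    if not s.strip():
        raise ValueError("empty newick string")
    return TreeNode.read(io.StringIO(s), format="newick")
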
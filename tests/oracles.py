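"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by exhaustive enumeration or naive
recounting, sharing no code with the implementation paths they check.
"""

from __future__ import annotations

import random


# ----------------------------------------------------------------------
# exhaustive global alignment (affine gaps), for short sequences only
# ----------------------------------------------------------------------

def brute_force_align_score(a, b, matrix, gap_open=10.0, gap_extend=0.5):
    """Best global alignment score by enumerating every alignment path.

    A gap of length L costs ``gap_open + (L - 1) * gap_extend``; end gaps
    are penalized.  Exponential: only for len <= ~8.
    """
    best = [float("-inf")]

    def rec(i, j, prev, score):
        if i == len(a) and j == len(b):
            if score > best[0]:
                best[0] = score
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, "M", score + matrix[a[i], b[j]])
        if i < len(a):  # gap in b
            cost = gap_extend if prev == "A" else gap_open
            rec(i + 1, j, "A", score - cost)
        if j < len(b):  # gap in a
            cost = gap_extend if prev == "B" else gap_open
            rec(i, j + 1, "B", score - cost)

    rec(0, 0, None, 0.0)
    return best[0]


# ----------------------------------------------------------------------
# exhaustive ORF enumeration
# ----------------------------------------------------------------------

_STOPS = {"TAA", "TAG", "TGA"}
_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s):
    return s.translate(_COMP)[::-1]


def _orfs_one_strand(seq):
    """Every ATG...stop (or ATG...end) span: (0-based start, length, open_ended).

    For in-frame ATGs sharing a stop, all spans are listed; the caller takes
    the max, which matches "longest ORF" semantics.
    """
    spans = []
    n = len(seq)
    for start in range(n - 2):
        if seq[start : start + 3] != "ATG":
            continue
        end = None
        for i in range(start + 3, n - 2, 3):
            if seq[i : i + 3] in _STOPS:
                end = i + 3
                break
        if end is None:
            usable = n - start
            usable -= usable % 3
            spans.append((start, usable, True))
        else:
            spans.append((start, end - start, False))
    return spans


def brute_force_longest_orf(nt, both_strands=True):
    """(length_bp, strand, start_1based) of the longest ORF, spec tie-breaks."""
    seq = nt.upper()
    candidates = []
    for s0, length, open_ended in _orfs_one_strand(seq):
        candidates.append((length, 0, s0 + 1, "+", open_ended))
    if both_strands:
        rc = _revcomp(seq)
        for s0, length, open_ended in _orfs_one_strand(rc):
            start_fwd = len(seq) - (s0 + length) + 1
            candidates.append((length, 1, start_fwd, "-", open_ended))
    if not candidates:
        return (0, "+", 0, False)
    length, _, start, strand, open_ended = max(
        candidates, key=lambda c: (c[0], -c[1], -c[2])
    )
    return (length, strand, start, open_ended)


# ----------------------------------------------------------------------
# random additive trees for NJ exactness checks
# ----------------------------------------------------------------------

class _Node:
    __slots__ = ("children", "length", "name")

    def __init__(self, name=None, length=0.0):
        self.children = []
        self.length = length
        self.name = name


def random_additive_tree(n_taxa, rng: random.Random):
    """A random binary tree with strictly positive branch lengths and its
    exact leaf-to-leaf path-length matrix.

    Returns (taxa, {frozenset({a, b}): distance}).
    """
    nodes = [_Node(name=f"T{i}") for i in range(n_taxa)]
    # leaf paths to current subtree roots
    below = {id(nd): {nd.name: 0.0} for nd in nodes}
    while len(nodes) > 1:
        i, j = sorted(rng.sample(range(len(nodes)), 2))
        a, b = nodes[i], nodes[j]
        la, lb = rng.uniform(0.1, 1.0), rng.uniform(0.1, 1.0)
        parent = _Node()
        a.length, b.length = la, lb
        parent.children = [a, b]
        below[id(parent)] = {
            **{k: v + la for k, v in below[id(a)].items()},
            **{k: v + lb for k, v in below[id(b)].items()},
        }
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)] + [parent]
    root = nodes[0]

    dist = {}

    def collect(node):
        if not node.children:
            return {node.name: 0.0}
        sub = []
        for ch in node.children:
            d = {k: v + ch.length for k, v in collect(ch).items()}
            sub.append(d)
        merged = {}
        for k in range(len(sub)):
            for m in range(k + 1, len(sub)):
                for x, dx in sub[k].items():
                    for y, dy in sub[m].items():
                        dist[frozenset((x, y))] = dx + dy
            merged.update(sub[k])
        return merged

    collect(root)
    taxa = [f"T{i}" for i in range(n_taxa)]
    return taxa, dist


# ----------------------------------------------------------------------
# naive average-linkage trace
# ----------------------------------------------------------------------

def naive_average_linkage_merge_order(points):
    """Merge order of average-linkage clustering by direct recomputation.

    ``points`` is a list of vectors; returns a list of frozensets of the
    original indices merged at each step.
    """
    import math

    clusters = [frozenset([i]) for i in range(len(points))]

    def d(x, y):
        return math.dist(points[x], points[y])

    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                avg = sum(d(x, y) for x in clusters[i] for y in clusters[j]) / (
                    len(clusters[i]) * len(clusters[j])
                )
                if best is None or avg < best[0] - 1e-12:
                    best = (avg, i, j)
        _, i, j = best
        merged = clusters[i] | clusters[j]
        merges.append(merged)
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return merges
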
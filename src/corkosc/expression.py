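"""TPM standardization, profile clustering, and tissue-specificity calls.

Expression support for a candidate gene is summarized by standardizing each
gene's TPM profile across samples to z-scores (sample standard deviation,
n-1 denominator) and averaging z per tissue.  Tissue-level means are then
banded: ``high`` (z >= 0.9, e.g. phellem-enhanced cork biosynthesis genes),
``moderate`` (0.2 <= z <= 0.7), ``low`` (z <= -0.2), and ``intermediate``
for values between bands.  A gene's *enhanced tissue* is the unique tissue
classified high; zero or multiple high tissues give no call.

Rows with zero variance cannot be standardized; they are dropped and
reported rather than silently propagated as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "ZScoreResult",
    "SpecificityCall",
    "ClusterResult",
    "zscores",
    "call_specificity",
    "cluster_profiles",
    "read_tpm_matrix",
    "read_tissue_map",
]


@dataclass(frozen=True)
class ZScoreResult:
    """Standardized matrix plus the genes dropped for zero variance."""

    z: pd.DataFrame
    dropped: tuple[str, ...]


def read_tpm_matrix(path: str | Path) -> pd.DataFrame:
    """Tab-delimited genes x samples TPM table, gene ids in the first column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValueError("TPM matrix contains missing values")
    if (df.values < 0).any():
        raise ValueError("TPM values must be non-negative")
    return df


def read_tissue_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "tissue"])
    return dict(zip(df["sample"], df["tissue"]))


def zscores(em: pd.DataFrame, log_transform: bool = False) -> ZScoreResult:
    """Per-gene standardization of a genes x samples matrix.

    ``log_transform`` applies log2(TPM + 1) before standardizing (off by
    default: published cork-tissue heatmaps standardize TPM directly).
    """
    if em.shape[1] < 2:
        raise ValueError("standardization requires at least 2 samples")
    x = np.log2(em + 1.0) if log_transform else em.astype(float)
    sd = x.std(axis=1, ddof=1)
    # treat rows constant up to float rounding as zero-variance
    tol = 1e-12 * x.abs().mean(axis=1).clip(lower=1.0)
    constant = sd[sd <= tol].index
    kept = x.drop(index=constant)
    z = kept.sub(kept.mean(axis=1), axis=0).div(sd.drop(index=constant), axis=0)
    return ZScoreResult(z=z, dropped=tuple(constant))


@dataclass(frozen=True)
class SpecificityCall:
    gene: str
    tissue_means: Mapping[str, float]
    classes: Mapping[str, str]
    enhanced_tissue: str | None


def _classify(z: float, high: float, mod_low: float, mod_high: float, low: float) -> str:
    if z >= high:
        return "high"
    if mod_low <= z <= mod_high:
        return "moderate"
    if z <= low:
        return "low"
    return "intermediate"


def call_specificity(
    z: pd.DataFrame,
    tissue_map: Mapping[str, str],
    high: float = 0.9,
    mod_low: float = 0.2,
    mod_high: float = 0.7,
    low: float = -0.2,
) -> list[SpecificityCall]:
    """Band per-tissue mean z-scores and call each gene's enhanced tissue."""
    unmapped = [s for s in z.columns if s not in tissue_map]
    if unmapped:
        raise ValueError(f"samples with no tissue assignment: {unmapped}")
    tissues = pd.Series({s: tissue_map[s] for s in z.columns})
    means = z.T.groupby(tissues).mean().T  # genes x tissues
    calls = []
    for gene, row in means.iterrows():
        classes = {t: _classify(v, high, mod_low, mod_high, low) for t, v in row.items()}
        highs = [t for t, c in classes.items() if c == "high"]
        calls.append(
            SpecificityCall(
                gene=gene,
                tissue_means=dict(row),
                classes=classes,
                enhanced_tissue=highs[0] if len(highs) == 1 else None,
            )
        )
    return calls


@dataclass(frozen=True)
class ClusterResult:
    linkage: np.ndarray
    leaf_order: tuple[str, ...]
    newick: str


def _linkage_to_newick(node, labels) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _linkage_to_newick(node.get_left(), labels)
    right = _linkage_to_newick(node.get_right(), labels)
    dl = node.dist - node.get_left().dist
    dr = node.dist - node.get_right().dist
    return f"({left}:{dl:g},{right}:{dr:g})"


def cluster_profiles(z: pd.DataFrame, axis: str = "genes") -> ClusterResult:
    """Average-linkage agglomerative clustering of z-score profiles.

    ``axis='genes'`` clusters rows, ``'samples'`` clusters columns; distances
    are Euclidean.  SciPy's linkage is deterministic (ties resolved by the
    original observation order), so leaf order is reproducible.
    """
    if axis not in ("genes", "samples"):
        raise ValueError("axis must be 'genes' or 'samples'")
    mat = z if axis == "genes" else z.T
    if mat.shape[0] < 2:
        raise ValueError("need at least 2 items to cluster")
    lk = hierarchy.linkage(pdist(mat.values, metric="euclidean"), method="average")
    order = hierarchy.leaves_list(lk)
    labels = list(mat.index)
    tree = hierarchy.to_tree(lk)
    return ClusterResult(
        linkage=lk,
        leaf_order=tuple(labels[i] for i in order),
        newick=_linkage_to_newick(tree, labels) + ";",
    )
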
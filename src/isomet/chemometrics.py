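"""Chemometric stage: normalization chain, PCA, hierarchical clustering.

The normalization chain is the MetaboAnalyst-style fixed sequence -
sum-normalize each sample, log10-transform (zeros replaced by half the
smallest positive value in the table), then auto-scale each feature to
zero mean / unit variance. PCA is a plain SVD of the samples x features
matrix with a deterministic sign convention; clustering is agglomerative
(Ward on Euclidean by default) with deterministic tie handling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .spectra_io import FeatureTable

__all__ = [
    "ChemometricsConfig",
    "PcaResult",
    "HclusterResult",
    "normalize_table",
    "pca",
    "hcluster",
]


@dataclass(frozen=True)
class ChemometricsConfig:
    distance: str = "euclidean"
    linkage: str = "ward"
    n_components: int = 2


@dataclass
class PcaResult:
    scores: np.ndarray  # samples x components
    loadings: np.ndarray  # features x components
    explained_pct: np.ndarray  # per-component % of total variance
    samples: list[str]
    feature_ids: list[str]


@dataclass
class HclusterResult:
    merges: np.ndarray  # scipy linkage matrix (n-1, 4)
    samples: list[str]

    def cut(self, k: int) -> dict[str, int]:
        """Flat cluster labels (1..k) per sample at ``k`` clusters."""
        labels = hierarchy.fcluster(self.merges, t=k, criterion="maxclust")
        return dict(zip(self.samples, (int(v) for v in labels)))

    def newick(self) -> str:
        """Dendrogram as a Newick-style nested string (branch lengths = heights)."""
        tree = hierarchy.to_tree(self.merges)

        def walk(node, parent_height: float) -> str:
            length = parent_height - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                name = self.samples[node.id].replace(" ", "_")
                return f"{name}:{parent_height - 0.0:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{max(length, 0.0):.6g}"

        return walk(tree, tree.dist).rsplit(":", 1)[0] + ";"


def normalize_table(t: FeatureTable) -> FeatureTable:
    """Sum-normalize -> log10 -> auto-scale (the fixed chain, in order).

    Each sample column is scaled to unit sum; zeros are replaced by half
    the smallest positive value in the sum-normalized table before the
    log; each feature row is then mean-centered and scaled to unit (ddof=1)
    variance. Zero-variance rows are dropped. An all-zero sample column is
    an error naming the sample.
    """
    x = t.intensities.astype(float).copy()
    colsums = x.sum(axis=0)
    for j, s in enumerate(colsums):
        if s <= 0:
            raise ValueError(f"sample {t.samples[j]!r} has no positive intensities")
    x = x / colsums

    positive = x[x > 0]
    fill = positive.min() / 2.0
    x = np.log10(np.where(x > 0, x, fill))

    means = x.mean(axis=1, keepdims=True)
    sds = x.std(axis=1, ddof=1, keepdims=True)
    keep = (sds[:, 0] > 0) & np.isfinite(sds[:, 0])
    x = (x[keep] - means[keep]) / sds[keep]

    return FeatureTable(
        feature_ids=[fid for fid, k in zip(t.feature_ids, keep) if k],
        mz=t.mz[keep],
        rt=t.rt[keep],
        samples=list(t.samples),
        intensities=x,
    )


def pca(t: FeatureTable, n_components: int = 2) -> PcaResult:
    """SVD-based principal component analysis of the samples x features matrix.

    Input should already be normalized. Component signs are fixed by
    forcing the largest-magnitude loading of each component positive, so
    score plots are reproducible run to run.
    """
    x = t.intensities.T  # samples x features
    n, p = x.shape
    max_comp = min(n, p)
    if not (1 <= n_components <= max_comp):
        raise ValueError(f"n_components must be in [1, {max_comp}], got {n_components}")
    xc = x - x.mean(axis=0, keepdims=True)
    u, sv, vt = np.linalg.svd(xc, full_matrices=False)
    # deterministic sign: largest-|loading| entry of each component positive
    for c in range(len(sv)):
        pivot = np.argmax(np.abs(vt[c]))
        if vt[c, pivot] < 0:
            vt[c] = -vt[c]
            u[:, c] = -u[:, c]
    var = sv**2
    explained = 100.0 * var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    scores = u * sv
    return PcaResult(
        scores=scores[:, :n_components],
        loadings=vt[:n_components].T,
        explained_pct=explained[:n_components],
        samples=list(t.samples),
        feature_ids=list(t.feature_ids),
    )


def full_pca(t: FeatureTable) -> PcaResult:
    """PCA with every available component (for reconstruction checks)."""
    return pca(t, n_components=min(t.n_samples, t.n_features))


def hcluster(
    t: FeatureTable, config: ChemometricsConfig = ChemometricsConfig()
) -> HclusterResult:
    """Agglomerative clustering of samples on the normalized table."""
    if t.n_samples < 2:
        raise ValueError("clustering needs at least 2 samples")
    x = t.intensities.T  # samples x features
    d = pdist(x, metric=config.distance)
    merges = hierarchy.linkage(d, method=config.linkage)
    return HclusterResult(merges=merges, samples=list(t.samples))
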
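"""Cluster-validity indices, compression loss, and small statistical helpers.

The three cluster indices share one geometry: the center of a cluster is the
component-wise *median* of its points, ``d_B`` is the Euclidean
center-to-center distance between two clusters, and ``d_W`` is the mean
Euclidean distance of a cluster's points to its own center (a radius).
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.stats import norm
from sklearn.metrics import silhouette_samples

__all__ = [
    "cluster_geometry",
    "dunn_index",
    "silhouette_index",
    "iid_index",
    "compression_loss",
    "compression_rate",
    "jaccard",
    "two_proportion_z",
]


def _check_clusters(points, labels):
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    if points.ndim != 2 or len(labels) != len(points):
        raise ValueError("points must be n x d with one label per point")
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("cluster indices need >= 2 clusters")
    return points, labels, uniq


def cluster_geometry(points, labels):
    """Median centers, pairwise center distances, and mean within radii."""
    points, labels, uniq = _check_clusters(points, labels)
    centers = {k: np.median(points[labels == k], axis=0) for k in uniq}
    d_b = {
        (a, b): float(np.linalg.norm(centers[a] - centers[b]))
        for a, b in itertools.combinations(uniq, 2)
    }
    d_w = {
        k: float(np.linalg.norm(points[labels == k] - centers[k], axis=1).mean())
        for k in uniq
    }
    return centers, d_b, d_w


def dunn_index(points, labels) -> float:
    """Minimal between-cluster center distance over the largest within radius."""
    _, d_b, d_w = cluster_geometry(points, labels)
    denom = max(d_w.values())
    if denom == 0:
        raise ValueError("all clusters are single points; Dunn index undefined")
    return min(d_b.values()) / denom


def iid_index(points, labels) -> float:
    """Inter-intra distance index: mean d_B over mean d_W.

    The between mean runs over the K(K-1)/2 unordered cluster pairs, the
    within mean over the K clusters.
    """
    _, d_b, d_w = cluster_geometry(points, labels)
    denom = float(np.mean(list(d_w.values())))
    if denom == 0:
        raise ValueError("all clusters are single points; IID index undefined")
    return float(np.mean(list(d_b.values()))) / denom


def silhouette_index(points, labels) -> float:
    """Macro-averaged silhouette: mean of the per-cluster mean silhouettes.

    Unlike the global sample mean, each cluster contributes equally
    regardless of its size. Singleton clusters contribute silhouette 0.
    """
    points, labels, uniq = _check_clusters(points, labels)
    s = silhouette_samples(points, labels)
    return float(np.mean([s[labels == k].mean() for k in uniq]))


def compression_rate(n_features: int, n_supersets: int) -> float:
    """Percent dimensionality reduction from genes to supersets."""
    return 100.0 * (1.0 - n_supersets / n_features)


def compression_loss(score_genes: float, score_supersets: float) -> float:
    """Percent drop of a validity index when genes are replaced by supersets."""
    if score_genes == 0:
        raise ValueError("gene-level index score is zero; loss undefined")
    return 100.0 * (score_genes - score_supersets) / score_genes


def jaccard(a, b) -> float:
    """|a ∩ b| / |a ∪ b| for two name sets."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        raise ValueError("Jaccard of two empty sets is undefined")
    return len(a & b) / len(union)


def two_proportion_z(x1: int, n1: int, x2: int, n2: int, alternative: str = "greater"):
    """Pooled two-proportion z-test without continuity correction.

    ``alternative='greater'`` gives the one-sided upper-tail p for
    H1: p1 > p2; ``'two-sided'`` doubles the smaller tail.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("trial counts must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("successes must lie in [0, n]")
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        raise ValueError("pooled proportion of 0 or 1; z-test undefined")
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (x1 / n1 - x2 / n2) / se
    if alternative == "greater":
        p = float(norm.sf(z))
    elif alternative == "less":
        p = float(norm.cdf(z))
    elif alternative == "two-sided":
        p = float(2 * norm.sf(abs(z)))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(z), p
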
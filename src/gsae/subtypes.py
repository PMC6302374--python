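"""Subtype discovery on superset scores and gene-set decomposition.

The workflow mirrors exploratory tumour-subtype analysis: embed the
superset scores into 2-D with t-SNE, cluster the embedding with HDBSCAN
(low-density samples become noise and are dropped downstream), find
supersets that separate one cluster ("group 1") from the union of the
others ("group 2") with a location-shifted one-tailed Mann-Whitney test,
and rank the gene sets inside each significant superset by their
contribution ``gsScore = (mu1 - mu2) * w``, where ``mu1``/``mu2`` are the
group means of the gene-set score and ``w`` the learned gene-set-to-superset
weight. Gene sets beyond ``k_sd`` standard deviations of a superset's
gsScore distribution are its high-impact members.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.cluster import HDBSCAN
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

logger = logging.getLogger("gsae")

NOISE = -1  # HDBSCAN noise label; such samples are excluded downstream

__all__ = [
    "NOISE",
    "DifferentialSuperset",
    "shifted_mww",
    "embed_2d",
    "cluster_embedding",
    "differential_supersets",
    "gs_score",
    "high_impact_gene_sets",
    "overlap_sets",
]


@dataclass
class DifferentialSuperset:
    """A superset significantly shifted in group 1 versus the rest."""

    index: int
    direction: str  # "up" | "down"
    p_value: float
    mu: float


def shifted_mww(x, y, mu: float = 0.0, alternative: str = "greater") -> float:
    """One-tailed Mann-Whitney U p-value with a location shift.

    ``alternative='greater'`` tests H1: x exceeds y by more than ``mu``.
    Exact enumeration is used when both groups have <= 8 observations and
    the shifted data are tie-free; otherwise the tie-corrected normal
    approximation.
    """
    x = np.asarray(x, dtype=float) - mu
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        raise ValueError("all observations tied; MWW undefined")
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (max(len(x), len(y)) <= 8 and tie_free) else "asymptotic"
    return float(mannwhitneyu(x, y, alternative=alternative, method=method).pvalue)


def embed_2d(
    matrix,
    seed: int = 0,
    perplexity: float = 30.0,
    pca_init_dim: int | None = None,
) -> np.ndarray:
    """t-SNE embedding into 2-D, optionally preceded by a PCA projection.

    ``pca_init_dim`` is meant for raw logTPM inputs (project to that many
    principal components first); superset scores are embedded directly.
    Deterministic given ``seed``.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if n < 5:
        raise ValueError("t-SNE needs at least 5 samples")
    if perplexity >= n / 3:
        raise ValueError(f"perplexity {perplexity} too large for {n} samples (needs < n/3)")
    if pca_init_dim is not None:
        k = min(pca_init_dim, *matrix.shape)
        matrix = PCA(n_components=k, random_state=seed).fit_transform(matrix)
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=seed, init="pca")
    return tsne.fit_transform(matrix)


def cluster_embedding(coords, min_cluster_size: int | None = None) -> np.ndarray:
    """HDBSCAN labels over a 2-D embedding; ambiguous samples become NOISE (-1).

    Default ``min_cluster_size`` is max(10, 1% of samples).
    """
    coords = np.asarray(coords, dtype=float)
    if min_cluster_size is None:
        min_cluster_size = max(10, int(0.01 * len(coords)))
    labels = HDBSCAN(min_cluster_size=min_cluster_size).fit_predict(coords)
    n_clusters = len(set(labels) - {NOISE})
    logger.info(
        "HDBSCAN: %d clusters, %d noise samples of %d",
        n_clusters, int((labels == NOISE).sum()), len(labels),
    )
    return labels


def _split_groups(values: np.ndarray, labels, group1):
    labels = np.asarray(labels)
    in1 = labels == group1
    in2 = (labels != group1) & (labels != NOISE)
    if not in1.any() or not in2.any():
        raise ValueError("group 1 and its complement must both be non-empty after noise removal")
    return values[in1], values[in2]


def differential_supersets(
    scores,
    labels,
    group1,
    mu: float = 9.0,
    alpha: float = 0.01,
) -> list[DifferentialSuperset]:
    """Screen supersets for a one-group shift of at least ``mu``.

    For every superset column, test H1: group-1 scores exceed the pooled
    other clusters by more than ``mu`` (up direction) and the mirror-image
    alternative (down direction); keep supersets whose one-tailed p-value
    is below ``alpha``. ``mu`` sets the stringency — larger values demand a
    larger separation. Noise samples are excluded; all-tied supersets are
    skipped with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    results = []
    for j in range(scores.shape[1]):
        g1, g2 = _split_groups(scores[:, j], labels, group1)
        try:
            p_up = shifted_mww(g1, g2, mu=mu, alternative="greater")
            p_down = shifted_mww(g1, g2, mu=-mu, alternative="less")
        except ValueError:
            warnings.warn(f"superset {j} has all-tied scores; skipped")
            continue
        if p_up < alpha:
            results.append(DifferentialSuperset(j, "up", p_up, mu))
        elif p_down < alpha:
            results.append(DifferentialSuperset(j, "down", p_down, mu))
    return sorted(results, key=lambda r: r.p_value)


def gs_score(
    gene_set_scores,
    labels,
    group1,
    weights_to_superset,
    set_names: list[str] | None = None,
    pscore_shift: float = 0.5,
) -> pd.DataFrame:
    """Gene-set contributions to one superset, sorted by gsScore (descending).

    ``weights_to_superset`` is the column of the gene-set-to-superset weight
    matrix for the superset under study. The PScore column is -log10 of a
    one-tailed Mann-Whitney p-value with location shift ``pscore_shift``,
    taken in the direction of the observed group-mean difference.
    """
    scores = np.asarray(gene_set_scores, dtype=float)
    w = np.asarray(weights_to_superset, dtype=float)
    if scores.shape[1] != len(w):
        raise ValueError("weight vector length must equal the number of gene sets")
    if set_names is None:
        set_names = [f"GS{i}" for i in range(len(w))]
    rows = []
    for i, name in enumerate(set_names):
        g1, g2 = _split_groups(scores[:, i], labels, group1)
        mu1, mu2 = float(g1.mean()), float(g2.mean())
        try:
            if mu1 >= mu2:
                p = shifted_mww(g1, g2, mu=pscore_shift, alternative="greater")
            else:
                p = shifted_mww(g1, g2, mu=-pscore_shift, alternative="less")
        except ValueError:
            p = 1.0
        rows.append(
            {
                "gene_set": name,
                "PScore": -np.log10(max(p, np.finfo(float).tiny)) + 0.0,  # +0.0 avoids -0.0
                "gsScore": (mu1 - mu2) * w[i],
                "weight": w[i],
                "mu1": mu1,
                "mu2": mu2,
            }
        )
    table = pd.DataFrame(rows).sort_values("gsScore", ascending=False, kind="mergesort")
    return table.reset_index(drop=True)


def high_impact_gene_sets(table: pd.DataFrame, direction: str = "up", k_sd: float = 2.0) -> list[str]:
    """Gene sets whose gsScore lies beyond ``k_sd`` standard deviations.

    Up-supersets take the right tail (gsScore > k_sd * sd), down-supersets
    the left tail (gsScore < -k_sd * sd); the sd is over all gsScores in
    the superset's table.
    """
    if table.empty:
        raise ValueError("gsScore table is empty")
    sd = float(table["gsScore"].std(ddof=1)) if len(table) > 1 else 0.0
    if sd == 0:
        warnings.warn("gsScore standard deviation is zero; no high-impact gene sets")
        return []
    if direction == "up":
        hit = table["gsScore"] > k_sd * sd
    elif direction == "down":
        hit = table["gsScore"] < -k_sd * sd
    else:
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    return table.loc[hit, "gene_set"].tolist()


def overlap_sets(lists: list[list[str]]) -> dict[tuple[int, ...], list[str]]:
    """All intersection regions among >= 2 name lists.

    Returns a map from a membership pattern (1 = in list i) to the sorted
    names in exactly that region; empty regions are included with empty
    lists, the all-zero pattern is omitted.
    """
    if len(lists) < 2:
        raise ValueError("need at least two lists")
    sets = [set(l) for l in lists]
    regions = {
        pattern: [] for pattern in itertools.product((0, 1), repeat=len(sets))
        if any(pattern)
    }
    for name in set().union(*sets):
        pattern = tuple(int(name in s) for s in sets)
        regions[pattern].append(name)
    return {p: sorted(v) for p, v in regions.items()}
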
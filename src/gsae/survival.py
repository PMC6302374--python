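"""Median-split log-rank screening and the superset reproducibility protocol.

Each superset (or gene-set) score dichotomizes the cohort at its median;
a two-group log-rank test then asks whether the two halves have different
survival. Nodes passing a significance screen are "prognostic". The
reproducibility experiment splits a cohort 60/40, trains the autoencoder on
the training portion only, screens both portions independently, and
compares how well superset versus gene-set significance lists replicate
(Jaccard index, overlap proportion, one-sided two-proportion z-test).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test

from .data import ExpressionMatrix, GeneSetCollection, SurvivalTable, build_mask
from .metrics import jaccard as _jaccard
from .metrics import two_proportion_z
from .model import NetworkConfig, ScoreMatrices, GsaeModel, encode, fit_autoencoder
from .subtypes import gs_score

logger = logging.getLogger("gsae")

__all__ = [
    "PrognosticResult",
    "ReproducibilityResult",
    "median_split",
    "logrank",
    "prognostic_supersets",
    "rank_gene_sets_for_superset",
    "reproducibility_experiment",
    "km_curve",
]


@dataclass
class PrognosticResult:
    node: str
    statistic: float
    p_value: float
    n_low: int
    n_high: int


@dataclass
class LayerReproducibility:
    train_significant: list[str]
    test_significant: list[str]
    jaccard: float | None
    overlap_proportion: float | None


@dataclass
class ReproducibilityResult:
    superset: LayerReproducibility
    gene_set: LayerReproducibility
    z: float | None = None
    p_value: float | None = None
    counts: dict = field(default_factory=dict)


def median_split(values) -> np.ndarray:
    """Dichotomize at the median: 0 = low (value <= median), 1 = high.

    Samples exactly at the median fall in the low group. Degenerate scores
    (more than 90% of samples tied at the median) are an error.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 4:
        raise ValueError("median split needs >= 4 samples")
    med = float(np.median(values))
    if (values == med).mean() > 0.9:
        raise ValueError("more than 90% of values tied at the median; split degenerate")
    groups = (values > med).astype(int)
    if groups.all() or not groups.any():
        raise ValueError("median split produced an empty group")
    return groups


def logrank(survival: SurvivalTable, groups) -> tuple[float, float]:
    """Two-group log-rank test (Mantel-Haenszel chi-square, 1 df, two-sided)."""
    groups = np.asarray(groups)
    if len(groups) != len(survival):
        raise ValueError("group labels must align with the survival table")
    g0, g1 = groups == 0, groups == 1
    if not g0.any() or not g1.any():
        raise ValueError("both groups must be non-empty")
    if survival.event.sum() == 0:
        raise ValueError("no events observed; log-rank test undefined")
    res = logrank_test(
        survival.time[g0], survival.time[g1],
        event_observed_A=survival.event[g0], event_observed_B=survival.event[g1],
    )
    return float(res.test_statistic), float(res.p_value)


def _screen(scores: np.ndarray, names: list[str], survival: SurvivalTable, alpha: float):
    """Median-split log-rank per column; significant results ranked by p."""
    hits = []
    for j, name in enumerate(names):
        try:
            groups = median_split(scores[:, j])
        except ValueError:
            warnings.warn(f"node {name} has a degenerate median split; skipped")
            continue
        stat, p = logrank(survival, groups)
        if p < alpha:
            hits.append(
                PrognosticResult(name, stat, p, int((groups == 0).sum()), int(groups.sum()))
            )
    return sorted(hits, key=lambda r: r.p_value)


def prognostic_supersets(
    scores: ScoreMatrices, survival: SurvivalTable, alpha: float = 0.001
) -> list[PrognosticResult]:
    """Supersets whose median split separates survival at p < alpha."""
    names = [f"SS{j}" for j in range(scores.superset_scores.shape[1])]
    return _screen(scores.superset_scores, names, survival, alpha)


def prognostic_gene_sets(
    scores: ScoreMatrices, survival: SurvivalTable, alpha: float = 0.001
) -> list[PrognosticResult]:
    """Gene-set-layer analogue of :func:`prognostic_supersets`."""
    return _screen(scores.gene_set_scores, list(scores.set_names), survival, alpha)


def rank_gene_sets_for_superset(
    superset_index: int,
    scores: ScoreMatrices,
    survival: SurvivalTable,
    model: GsaeModel,
) -> pd.DataFrame:
    """gsScore ranking of gene sets within one prognostic superset.

    The two groups entering the gsScore formula are the median-split halves
    of the superset's own score (group 1 = high half). Each gene set also
    gets its own median-split log-rank p-value, as in the published
    per-superset tables (term, log-rank P, gsScore, weight).
    """
    ss = scores.superset_scores[:, superset_index]
    groups = median_split(ss)
    w = model.superset_weights[:, superset_index]
    table = gs_score(scores.gene_set_scores, groups, 1, w, set_names=scores.set_names)
    pvals = {}
    for j, name in enumerate(scores.set_names):
        try:
            g = median_split(scores.gene_set_scores[:, j])
            _, pvals[name] = logrank(survival, g)
        except ValueError:
            pvals[name] = np.nan
    table["logrank_p"] = table["gene_set"].map(pvals)
    return table


def km_curve(survival: SurvivalTable, groups) -> pd.DataFrame:
    """Kaplan-Meier curve data (time, at-risk, survival) per group, for plotting."""
    from lifelines import KaplanMeierFitter

    frames = []
    for g in np.unique(np.asarray(groups)):
        sel = np.asarray(groups) == g
        kmf = KaplanMeierFitter()
        kmf.fit(survival.time[sel], survival.event[sel])
        df = kmf.event_table.reset_index()[["event_at", "at_risk"]]
        df["survival"] = kmf.survival_function_.to_numpy().ravel()
        df["group"] = g
        frames.append(df.rename(columns={"event_at": "time"}))
    return pd.concat(frames, ignore_index=True)


def reproducibility_experiment(
    expr: ExpressionMatrix,
    survival: SurvivalTable,
    collection: GeneSetCollection,
    config: NetworkConfig | None = None,
    train_fraction: float = 0.6,
    alpha: float = 0.05,
    seed: int = 0,
) -> ReproducibilityResult:
    """Train/test replication of prognostic screening, supersets vs gene sets.

    A simple random ``train_fraction`` split (with ``seed``) yields the
    training cohort on which the autoencoder is fitted; both cohorts are
    then scored and screened independently at ``alpha``. For each layer the
    result records the significant node lists, their Jaccard index, and the
    overlap proportion |train ∩ test| / |train|; the z-test asks one-sided
    whether the superset proportion exceeds the gene-set proportion. A
    layer with zero train-significant nodes gets missing (None) proportion.
    """
    config = config or NetworkConfig()
    rng = np.random.default_rng(seed)
    n = expr.n_samples
    idx = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    if n_train < 10 or n - n_train < 10:
        raise ValueError("train/test split too small for screening")
    idx_train, idx_test = np.sort(idx[:n_train]), np.sort(idx[n_train:])

    expr_train = expr.subset_samples(idx_train)
    expr_test = expr.subset_samples(idx_test)
    surv_train = SurvivalTable(
        survival.time[idx_train], survival.event[idx_train],
        [survival.samples[i] for i in idx_train],
    )
    surv_test = SurvivalTable(
        survival.time[idx_test], survival.event[idx_test],
        [survival.samples[i] for i in idx_test],
    )

    mask, kept = build_mask(collection, expr_train)
    model = fit_autoencoder(expr_train, mask, config)
    sc_train = encode(model, expr_train)
    sc_test = encode(model, expr_test)

    layers = {}
    for layer_name, screen in (
        ("superset", prognostic_supersets),
        ("gene_set", prognostic_gene_sets),
    ):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # degenerate-node skips are expected here
            sig_train = [r.node for r in screen(sc_train, surv_train, alpha)]
            sig_test = [r.node for r in screen(sc_test, surv_test, alpha)]
        overlap = len(set(sig_train) & set(sig_test))
        layers[layer_name] = LayerReproducibility(
            sig_train,
            sig_test,
            _jaccard(sig_train, sig_test) if (sig_train or sig_test) else None,
            overlap / len(sig_train) if sig_train else None,
        )
    ss, gs = layers["superset"], layers["gene_set"]
    counts = {
        "superset_overlap": len(set(ss.train_significant) & set(ss.test_significant)),
        "superset_train": len(ss.train_significant),
        "gene_set_overlap": len(set(gs.train_significant) & set(gs.test_significant)),
        "gene_set_train": len(gs.train_significant),
    }
    z = p = None
    if counts["superset_train"] and counts["gene_set_train"]:
        try:
            z, p = two_proportion_z(
                counts["superset_overlap"], counts["superset_train"],
                counts["gene_set_overlap"], counts["gene_set_train"],
                alternative="greater",
            )
        except ValueError:
            pass  # pooled proportion 0 or 1: comparison undefined
    return ReproducibilityResult(ss, gs, z, p, counts)
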
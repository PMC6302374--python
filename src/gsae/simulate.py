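"""Synthetic logTPM cohorts with planted structure, for tests and demos.

The generators emulate the *shape* of preprocessed bulk RNA-seq inputs —
a samples x genes logTPM matrix, an overlapping gene-set collection, and a
right-censored survival table — not the marginal distributions or gene
identities of any real cohort. Baseline expression is truncated-normal
logTPM, ``max(0, N(mu0, sigma0))``; subtype structure is planted by adding
an effect ``delta`` to the member genes of group-specific gene sets, and
prognostic structure by coupling a latent per-sample program score both to
a block of member genes and to the event hazard of an exponential survival
model. Gene sets behave as co-expression modules: each set carries a
per-sample activity factor (sd ``module_sd``) added to its member genes,
the way pathway activity varies across tumours. Every generator is a pure
function of its spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .data import (
    DEFAULT_HORIZON_DAYS,
    ExpressionMatrix,
    GeneSetCollection,
    SurvivalTable,
    censor_survival,
)

__all__ = ["FixtureSpec", "make_collection", "make_subtype_data",
           "make_survival_expression", "make_survival_data"]


@dataclass
class FixtureSpec:
    """Study conditions for the synthetic cohort generators.

    Defaults give a small but realistic desk-scale cohort: 300 samples,
    400 genes, 30 sets of 15-25 genes, two balanced subtypes with 5 planted
    sets each upshifted by 2 logTPM units, baseline logTPM ~ max(0, N(2, 1))
    (so all genes pass the mu > 1, sigma > 0.5 filter), and an exponential
    survival model with ~900-day median survival and ~30% independent
    censoring before the five-year horizon.
    """

    n_samples: int = 300
    n_genes: int = 400
    n_sets: int = 30
    set_size_min: int = 15
    set_size_max: int = 25
    overlap_fraction: float = 0.0
    baseline_mean: float = 2.0
    baseline_sd: float = 1.0
    module_sd: float = 1.0
    n_groups: int = 2
    planted_sets_per_group: int = 5
    delta: float = 2.0
    program_n_sets: int = 3
    program_effect: float = 1.0
    baseline_hazard: float = np.log(2) / 900.0  # per day
    beta: float = 1.0
    censor_rate: float = 0.3
    horizon: float = DEFAULT_HORIZON_DAYS
    seed: int = 0

    def __post_init__(self):
        for name in ("n_samples", "n_genes", "n_sets", "set_size_min", "set_size_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.delta < 0 or self.program_effect < 0:
            raise ValueError("effect sizes must be >= 0")
        if not 0 <= self.overlap_fraction <= 1:
            raise ValueError("overlap_fraction must lie in [0, 1]")

    def with_(self, **kwargs) -> "FixtureSpec":
        return replace(self, **kwargs)


def _gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def make_collection(spec: FixtureSpec) -> GeneSetCollection:
    """Gene-set collection with controllable pairwise overlap.

    Set sizes are uniform in [set_size_min, set_size_max]. The first
    ``max(n_groups * planted_sets_per_group, program_n_sets)`` sets are
    *plantable*: they get mutually disjoint gene blocks that no background
    set touches, so a planted signature is an exclusive transcriptional
    module rather than smeared across the collection. Background sets draw
    at random from the remaining genes (incidental overlap only); with
    ``overlap_fraction`` f > 0 each background set additionally shares
    round(f * size) genes with the previous one, giving kappa clustering
    its positive cases. Requests that exhaust the gene pool are an error.
    """
    rng = np.random.default_rng(spec.seed)
    genes = np.array(_gene_names(spec.n_genes))
    sizes = rng.integers(spec.set_size_min, spec.set_size_max + 1, size=spec.n_sets)
    n_reserved = min(
        spec.n_sets, max(spec.n_groups * spec.planted_sets_per_group, spec.program_n_sets)
    )
    reserved_genes = int(sizes[:n_reserved].sum())
    background_pool = genes[reserved_genes:]
    if reserved_genes + (sizes[n_reserved:].max(initial=0)) > spec.n_genes:
        raise ValueError(
            f"gene pool of {spec.n_genes} too small for {n_reserved} disjoint "
            f"plantable sets plus background sets; raise n_genes"
        )
    collection = GeneSetCollection()
    cursor = 0
    prev: list[str] = []
    for i, size in enumerate(sizes):
        if i < n_reserved:
            members = list(genes[cursor : cursor + size])
            cursor += size
        else:
            n_shared = round(spec.overlap_fraction * size) if prev else 0
            n_shared = min(n_shared, len(prev), size)
            shared = list(rng.choice(prev, size=n_shared, replace=False)) if n_shared else []
            pool = np.setdiff1d(background_pool, shared)
            fresh = list(rng.choice(pool, size=size - n_shared, replace=False))
            members = shared + fresh
            prev = members
        collection.add(f"SET{i:03d}", members, f"synthetic set {i}")
    return collection


def _baseline(rng: np.random.Generator, n: int, p: int, spec: FixtureSpec) -> np.ndarray:
    return np.maximum(0.0, rng.normal(spec.baseline_mean, spec.baseline_sd, size=(n, p)))


def _member_columns(collection: GeneSetCollection, names: list[str], genes: list[str]) -> np.ndarray:
    index = {g: j for j, g in enumerate(genes)}
    cols = {index[g] for name in names for g in collection.members(name) if g in index}
    return np.fromiter(sorted(cols), dtype=int)


def _add_module_activity(
    rng: np.random.Generator,
    values: np.ndarray,
    collection: GeneSetCollection,
    genes: list[str],
    spec: FixtureSpec,
    skip: set[str] = frozenset(),
) -> None:
    """Per-sample pathway activity: each set's members share a N(0, module_sd) factor."""
    if spec.module_sd <= 0:
        return
    for name in collection:
        if name in skip:
            continue
        cols = _member_columns(collection, [name], genes)
        factor = rng.normal(0.0, spec.module_sd, size=values.shape[0])
        values[:, cols] += factor[:, None]


def make_subtype_data(
    spec: FixtureSpec, collection: GeneSetCollection
) -> tuple[ExpressionMatrix, np.ndarray, dict[int, list[str]]]:
    """Expression with planted subtype structure; returns (expr, labels, planted).

    Samples are split into ``n_groups`` balanced groups; group g's planted
    sets are ``planted_sets_per_group`` consecutive sets starting at
    g * planted_sets_per_group, and their member genes are shifted up by
    ``delta`` in that group. With delta = 0 the groups are exchangeable.
    """
    rng = np.random.default_rng(spec.seed + 1)
    genes = _gene_names(spec.n_genes)
    labels = np.repeat(np.arange(spec.n_groups), -(-spec.n_samples // spec.n_groups))
    labels = rng.permutation(labels[: spec.n_samples])
    values = _baseline(rng, spec.n_samples, spec.n_genes, spec)

    names = collection.names
    k = spec.planted_sets_per_group
    if spec.n_groups * k > len(names):
        raise ValueError("not enough gene sets to plant every group's block")
    planted = {g: names[g * k : (g + 1) * k] for g in range(spec.n_groups)}
    _add_module_activity(rng, values, collection, genes, spec)
    for g, set_names in planted.items():
        cols = _member_columns(collection, set_names, genes)
        values[np.ix_(labels == g, cols)] += spec.delta
    values = np.maximum(values, 0.0)
    expr = ExpressionMatrix(values, [f"S{i:04d}" for i in range(spec.n_samples)], genes)
    return expr, labels, planted


def make_survival_expression(
    spec: FixtureSpec, collection: GeneSetCollection
) -> tuple[ExpressionMatrix, np.ndarray, list[str]]:
    """Expression with a planted prognostic program.

    A latent per-sample score u ~ N(0, 1) is added (scaled by
    ``program_effect``) to the member genes of the first ``program_n_sets``
    sets; the same u later drives the event hazard in
    :func:`make_survival_data`. Returns (expr, u, program set names).
    """
    rng = np.random.default_rng(spec.seed + 2)
    genes = _gene_names(spec.n_genes)
    values = _baseline(rng, spec.n_samples, spec.n_genes, spec)
    u = rng.normal(size=spec.n_samples)
    program = collection.names[: spec.program_n_sets]
    _add_module_activity(rng, values, collection, genes, spec, skip=set(program))
    cols = _member_columns(collection, program, genes)
    values[:, cols] += spec.program_effect * u[:, None]
    values = np.maximum(values, 0.0)
    expr = ExpressionMatrix(values, [f"S{i:04d}" for i in range(spec.n_samples)], genes)
    return expr, u, program


def make_survival_data(spec: FixtureSpec, program_scores) -> SurvivalTable:
    """Exponential survival with hazard ∝ exp(beta * standardized score).

    Event times are Exponential with per-sample hazard
    ``baseline_hazard * exp(beta * z)``; censoring times are independent
    Exponential with hazard tuned so roughly ``censor_rate`` of samples are
    censored before their event when beta = 0, then everything is
    administratively censored at the horizon. ``censor_rate = 1`` leaves no
    events and is an error.
    """
    rng = np.random.default_rng(spec.seed + 3)
    z = np.asarray(program_scores, dtype=float)
    sd = z.std()
    z = (z - z.mean()) / sd if sd > 0 else z * 0.0
    if spec.censor_rate >= 1:
        raise ValueError("censor_rate of 1 leaves zero events")
    hazard = spec.baseline_hazard * np.exp(spec.beta * z)
    t_event = rng.exponential(1.0 / hazard)
    if spec.censor_rate > 0:
        h_c = spec.baseline_hazard * spec.censor_rate / (1.0 - spec.censor_rate)
        t_cens = rng.exponential(1.0 / h_c, size=len(z))
    else:
        t_cens = np.full(len(z), np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    time = np.maximum(time, 1e-3)  # guard against zero-day follow-up
    t, e = censor_survival(time, event, spec.horizon)
    if e.sum() == 0:
        raise ValueError("simulated cohort has zero events; lower censor_rate")
    return SurvivalTable(t, e, [f"S{i:04d}" for i in range(len(z))])
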
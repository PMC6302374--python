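"""Input formats, preprocessing, and the gene-set connectivity mask.

Expression data are handled as logTPM (log2(TPM + 1)) matrices with samples
on the rows and genes on the columns in memory; on disk the TSV convention
is genes as rows and samples as columns (the usual RNA-seq layout), with a
``transpose`` escape hatch. Gene-set collections use the MSigDB GMT dialect:
one set per line, ``name<TAB>description<TAB>gene1<TAB>gene2...``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

logger = logging.getLogger("gsae")

__all__ = [
    "GeneSetCollection",
    "ExpressionMatrix",
    "MembershipMask",
    "SurvivalTable",
    "read_gmt",
    "write_gmt",
    "read_expression",
    "read_clinical",
    "log_transform",
    "filter_genes",
    "censor_survival",
    "build_mask",
    "pca_project",
]

DEFAULT_HORIZON_DAYS = 1825  # five-year survival record


class GeneSetCollection:
    """Ordered, named gene sets with optional per-set descriptions.

    Iteration order is the file (insertion) order; set names are unique and
    member lists are duplicate-free (first occurrence wins).
    """

    def __init__(
        self,
        sets: dict[str, list[str]] | None = None,
        descriptions: dict[str, str] | None = None,
    ):
        self.sets: dict[str, list[str]] = {}
        self.descriptions: dict[str, str] = {}
        if sets:
            for name, members in sets.items():
                self.add(name, members, (descriptions or {}).get(name, ""))

    def add(self, name: str, members: list[str], description: str = "") -> None:
        if name in self.sets:
            raise ValueError(f"duplicate gene set name: {name!r}")
        deduped = list(dict.fromkeys(m.strip() for m in members if m.strip()))
        if not deduped:
            raise ValueError(f"gene set {name!r} has no members")
        self.sets[name] = deduped
        self.descriptions[name] = description

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def members(self, name: str) -> list[str]:
        return self.sets[name]

    def subset(self, names: list[str]) -> "GeneSetCollection":
        """New collection with the given sets, preserving this one's order."""
        keep = set(names)
        out = GeneSetCollection()
        for name in self.sets:
            if name in keep:
                out.add(name, self.sets[name], self.descriptions[name])
        return out

    def universe(self) -> list[str]:
        """Union of all member genes, in first-appearance order."""
        seen: dict[str, None] = {}
        for members in self.sets.values():
            for g in members:
                seen.setdefault(g)
        return list(seen)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __repr__(self) -> str:
        return f"GeneSetCollection({len(self)} sets)"


@dataclass
class ExpressionMatrix:
    """Samples x genes logTPM matrix with axis labels.

    ``values[i, j]`` is the logTPM of gene ``genes[j]`` in sample
    ``samples[i]``. Values are finite and nonnegative; gene symbols unique.
    """

    values: np.ndarray
    samples: list[str]
    genes: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.samples = [str(s) for s in self.samples]
        self.genes = [str(g).strip() for g in self.genes]
        if self.values.ndim != 2:
            raise ValueError("expression values must be 2-D (samples x genes)")
        if self.values.shape != (len(self.samples), len(self.genes)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.samples)} samples x {len(self.genes)} genes"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene symbols must be unique")
        if not np.isfinite(self.values).all():
            raise ValueError("expression matrix contains missing/non-finite values")
        if (self.values < 0).any():
            raise ValueError("logTPM values must be nonnegative")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.samples, columns=self.genes)

    def subset_samples(self, idx: np.ndarray) -> "ExpressionMatrix":
        idx = np.asarray(idx)
        return ExpressionMatrix(
            self.values[idx], [self.samples[i] for i in idx], list(self.genes)
        )


@dataclass
class MembershipMask:
    """Binary genes x gene-sets connectivity matrix.

    ``mask[g, s] = 1`` iff gene ``genes[g]`` belongs to set ``set_names[s]``.
    Row order matches an ExpressionMatrix, column order a GeneSetCollection.
    """

    mask: np.ndarray
    genes: list[str]
    set_names: list[str]

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=float)
        if self.mask.shape != (len(self.genes), len(self.set_names)):
            raise ValueError("mask shape does not match gene/set label counts")
        vals = np.unique(self.mask)
        if not np.isin(vals, (0.0, 1.0)).all():
            raise ValueError("mask entries must be 0 or 1")
        if (self.mask.sum(axis=0) < 1).any():
            raise ValueError("every gene set column must connect to >= 1 gene")

    @property
    def n_genes(self) -> int:
        return self.mask.shape[0]

    @property
    def n_sets(self) -> int:
        return self.mask.shape[1]


@dataclass
class SurvivalTable:
    """Per-sample follow-up time (days) and death-event flag.

    Times are positive and, after :func:`censor_survival`, never exceed the
    horizon; events recorded beyond the horizon are stored censored at it.
    """

    time: np.ndarray
    event: np.ndarray
    samples: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if self.time.shape != self.event.shape or self.time.ndim != 1:
            raise ValueError("time and event must be 1-D and aligned")
        if not self.samples:
            self.samples = [f"S{i}" for i in range(len(self.time))]
        if len(self.samples) != len(self.time):
            raise ValueError("sample ids do not match table length")
        if (self.time <= 0).any():
            raise ValueError("survival times must be positive")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event flags must be 0 or 1")

    def __len__(self) -> int:
        return len(self.time)

    def censored(self, horizon: float = DEFAULT_HORIZON_DAYS) -> "SurvivalTable":
        t, e = censor_survival(self.time, self.event, horizon)
        return SurvivalTable(t, e, list(self.samples))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample": self.samples, "time_days": self.time, "event": self.event}
        )


# ---------------------------------------------------------------------------
# readers / writers


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT gene-set file (MSigDB dialect).

    Each line: ``name<TAB>description<TAB>gene1<TAB>gene2...``. Within-set
    duplicate symbols are collapsed; duplicate set names raise with the line
    number; lines with fewer than three fields raise.
    """
    collection = GeneSetCollection()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno} has {len(fields)} fields; "
                    "expected name, description, and >= 1 gene"
                )
            name, desc, genes = fields[0], fields[1], fields[2:]
            if name in collection:
                raise ValueError(f"{path}: duplicate gene set name {name!r} at line {lineno}")
            collection.add(name, genes, desc)
    logger.info("read %d gene sets from %s", len(collection), path)
    return collection


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in collection:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *collection.members(name)]) + "\n")


def read_expression(path, transpose: bool = False, assume_log: bool = True) -> ExpressionMatrix:
    """Read an expression TSV (genes as rows, samples as columns by default).

    Set ``transpose=True`` if the file is samples x genes. With
    ``assume_log=False`` the values are treated as raw TPM and passed through
    :func:`log_transform`.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValueError(f"{path}: expression table contains missing values")
    if not transpose:
        df = df.T  # samples x genes in memory
    expr = ExpressionMatrix(
        df.to_numpy(dtype=float), list(df.index), list(df.columns)
    ) if assume_log else log_transform(
        df.to_numpy(dtype=float), samples=list(df.index), genes=list(df.columns)
    )
    logger.info("read expression: %d samples x %d genes", expr.n_samples, expr.n_genes)
    return expr


def write_expression(expr: ExpressionMatrix, path) -> None:
    # on-disk convention: genes as rows
    expr.to_frame().T.to_csv(path, sep="\t", index_label="gene")


def read_clinical(path, horizon: float = DEFAULT_HORIZON_DAYS) -> tuple[SurvivalTable, pd.Series | None]:
    """Read a clinical TSV with columns sample, time_days, event[, label].

    Returns the horizon-censored survival table and, when present, the
    per-sample label column (e.g. a subtype annotation).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "time_days", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing clinical columns {sorted(missing)}")
    table = SurvivalTable(
        df["time_days"].to_numpy(float),
        df["event"].to_numpy(int),
        [str(s) for s in df["sample"]],
    ).censored(horizon)
    labels = df.set_index("sample")["label"] if "label" in df.columns else None
    logger.info("read clinical table: %d samples, %d events", len(table), int(table.event.sum()))
    return table, labels


# ---------------------------------------------------------------------------
# preprocessing


def log_transform(
    tpm_values: np.ndarray,
    samples: list[str] | None = None,
    genes: list[str] | None = None,
) -> ExpressionMatrix:
    """Elementwise log2(TPM + 1). Negative inputs are an error."""
    values = np.asarray(tpm_values, dtype=float)
    if (values < 0).any():
        raise ValueError("TPM values must be nonnegative")
    log_values = np.log2(values + 1.0)
    if samples is None:
        samples = [f"S{i}" for i in range(values.shape[0])]
    if genes is None:
        genes = [f"G{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(log_values, samples, genes)


def filter_genes(
    expr: ExpressionMatrix, mu_min: float = 1.0, sigma_min: float = 0.5
) -> ExpressionMatrix:
    """Keep genes with across-sample mean > mu_min and sd > sigma_min.

    Inequalities are strict; the standard deviation uses the n-1 denominator.
    """
    mu = expr.values.mean(axis=0)
    sigma = expr.values.std(axis=0, ddof=1)
    keep = (mu > mu_min) & (sigma > sigma_min)
    if not keep.any():
        raise ValueError(
            f"no genes pass mu > {mu_min} and sigma > {sigma_min}; "
            "lower the thresholds for this data set"
        )
    dropped = int((~keep).sum())
    if dropped:
        logger.info("filter_genes: dropped %d of %d genes", dropped, expr.n_genes)
    return ExpressionMatrix(
        expr.values[:, keep],
        list(expr.samples),
        [g for g, k in zip(expr.genes, keep) if k],
    )


def censor_survival(time, event, horizon: float = DEFAULT_HORIZON_DAYS):
    """Apply administrative censoring at ``horizon`` days.

    Observations strictly beyond the horizon become censored at the horizon;
    an event exactly at the horizon remains an event. Accepts scalars or
    arrays and returns the same shape.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if (t <= 0).any():
        raise ValueError("survival times must be positive")
    beyond = t > horizon
    t_out = np.where(beyond, float(horizon), t)
    e_out = np.where(beyond, 0, e)
    if np.isscalar(time) or t.ndim == 0:
        return float(t_out), int(e_out)
    return t_out, e_out


def build_mask(collection: GeneSetCollection, expr: ExpressionMatrix) -> tuple[MembershipMask, GeneSetCollection]:
    """Build the gene x gene-set connectivity mask for the encoder layer.

    Only genes belonging to a set connect to that set's node. Sets with an
    empty intersection against the expression genes are dropped with a
    warning (so arbitrary GMT files work against any matrix); the returned
    collection contains exactly the surviving sets, in input order.
    """
    gene_index = {g: i for i, g in enumerate(expr.genes)}
    columns, kept = [], []
    for name in collection:
        rows = [gene_index[g] for g in collection.members(name) if g in gene_index]
        if not rows:
            logger.warning("gene set %r shares no genes with the expression matrix; dropped", name)
            continue
        col = np.zeros(expr.n_genes)
        col[rows] = 1.0
        columns.append(col)
        kept.append(name)
    if not kept:
        raise ValueError("no gene set overlaps the expression matrix")
    mask = MembershipMask(np.column_stack(columns), list(expr.genes), kept)
    return mask, collection.subset(kept)


def pca_project(expr: ExpressionMatrix, k: int = 500, seed: int = 0) -> np.ndarray:
    """Project samples onto the top-k principal components of the gene axis."""
    bound = min(expr.n_samples, expr.n_genes)
    if k > bound:
        raise ValueError(f"k={k} exceeds min(n_samples, n_genes)={bound}")
    return PCA(n_components=k, random_state=seed).fit_transform(expr.values)
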
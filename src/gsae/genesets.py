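"""Resolve dependencies among gene sets before building the gene-set layer.

Curated collections (e.g. MSigDB CGP) contain many near-duplicate signatures.
The preparation pipeline is: drop sets outside a size window (default 15-500
genes, the classic enrichment-analysis window), measure pairwise similarity
with Cohen's kappa over the collection's gene universe, connect pairs whose
kappa is positive and significant (default P < 1e-7), take connected
components as redundancy clusters, and keep the largest member of each
cluster as its representative.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data import GeneSetCollection

logger = logging.getLogger("gsae")

__all__ = [
    "KappaResult",
    "GeneSetCluster",
    "filter_by_size",
    "kappa_similarity",
    "cluster_gene_sets",
    "select_representatives",
    "deduplicate",
]


@dataclass
class KappaResult:
    """Cohen's kappa between two membership vectors over a gene universe.

    ``contingency`` counts (both, only_a, only_b, neither) genes and sums to
    the universe size; ``p_value`` is one-sided for H1: kappa > 0.
    """

    kappa: float
    p_value: float
    contingency: tuple[int, int, int, int]


@dataclass
class GeneSetCluster:
    """A redundancy cluster with its largest member as representative."""

    members: list[str]
    representative: str


def filter_by_size(
    collection: GeneSetCollection, min_size: int = 15, max_size: int = 500
) -> GeneSetCollection:
    """Keep sets with min_size <= |set| <= max_size (raw member counts)."""
    keep = [n for n in collection if min_size <= len(collection.members(n)) <= max_size]
    if not keep:
        raise ValueError(
            f"no gene set has between {min_size} and {max_size} members"
        )
    dropped = len(collection) - len(keep)
    if dropped:
        logger.info("filter_by_size: dropped %d of %d sets", dropped, len(collection))
    return collection.subset(keep)


def kappa_similarity(set_a, set_b, universe) -> KappaResult:
    """Chance-corrected agreement of two gene sets as binary annotations.

    Treats membership in each set as a rater labelling every universe gene
    in/out, and computes Cohen's kappa from the resulting 2x2 contingency.
    Significance is a one-sided upper-tail z-test of H0: kappa = 0 using the
    large-sample null standard error computed from the table's marginals
    (Fleiss), so highly overlapping sets over a big universe get very small
    p-values.
    """
    universe = list(universe)
    n = len(universe)
    if n < 2:
        raise ValueError("universe must contain >= 2 genes")
    a_set, b_set = set(set_a), set(set_b)
    if not a_set <= set(universe) or not b_set <= set(universe):
        raise ValueError("both gene sets must be subsets of the universe")
    if not a_set or not b_set:
        raise ValueError("gene sets must be non-empty for kappa")
    if len(a_set) == n or len(b_set) == n:
        raise ValueError("a set equal to the whole universe makes kappa degenerate")

    both = len(a_set & b_set)
    only_a = len(a_set - b_set)
    only_b = len(b_set - a_set)
    neither = n - both - only_a - only_b

    p_o = (both + neither) / n
    pa, pb = len(a_set) / n, len(b_set) / n
    p_e = pa * pb + (1 - pa) * (1 - pb)
    kappa = (p_o - p_e) / (1 - p_e)

    # Fleiss null variance from the marginal proportions of the 2x2 table
    marg = ((pa, pb), (1 - pa, 1 - pb))
    s = sum(row * col * (row + col) for row, col in marg)
    var0 = (p_e + p_e**2 - s) / (n * (1 - p_e) ** 2)
    if var0 <= 0:
        p_value = 1.0 if kappa <= 0 else 0.0
    else:
        z = kappa / np.sqrt(var0)
        p_value = float(norm.sf(z))
    return KappaResult(float(kappa), max(p_value, np.finfo(float).tiny), (both, only_a, only_b, neither))


def cluster_gene_sets(
    collection: GeneSetCollection,
    universe=None,
    p_threshold: float = 1e-7,
) -> list[GeneSetCluster]:
    """Cluster redundant gene sets by significant positive kappa.

    An edge joins every pair with kappa > 0 and p < ``p_threshold``; clusters
    are the connected components of that graph (singletons allowed). The
    default universe is the union of member genes across the collection, so
    the result does not depend on any expression matrix.
    """
    names = collection.names
    universe = list(universe) if universe is not None else collection.universe()
    parent = {n: n for n in names}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    n_edges = 0
    for a, b in itertools.combinations(names, 2):
        res = kappa_similarity(collection.members(a), collection.members(b), universe)
        if res.kappa > 0 and res.p_value < p_threshold:
            parent[find(a)] = find(b)
            n_edges += 1
    groups: dict[str, list[str]] = {}
    for n in names:
        groups.setdefault(find(n), []).append(n)
    logger.info(
        "kappa clustering: %d sets, %d significant pairs, %d clusters",
        len(names), n_edges, len(groups),
    )
    clusters = []
    for members in groups.values():
        # largest set wins; size ties go to the lexicographically smaller name
        rep = min(members, key=lambda n: (-len(collection.members(n)), n))
        clusters.append(GeneSetCluster(sorted(members), rep))
    return clusters


def select_representatives(
    clusters: list[GeneSetCluster], collection: GeneSetCollection
) -> GeneSetCollection:
    """Reduce to one representative per cluster, preserving file order."""
    clustered = [m for c in clusters for m in c.members]
    if sorted(clustered) != sorted(collection.names):
        raise ValueError("clusters must partition the collection")
    reps = {c.representative for c in clusters}
    return collection.subset([n for n in collection if n in reps])


def deduplicate(
    collection: GeneSetCollection,
    min_size: int = 15,
    max_size: int = 500,
    p_threshold: float = 1e-7,
) -> tuple[GeneSetCollection, list[GeneSetCluster]]:
    """Full preparation pipeline: size filter, kappa clustering, representatives."""
    sized = filter_by_size(collection, min_size, max_size)
    clusters = cluster_gene_sets(sized, p_threshold=p_threshold)
    reduced = select_representatives(clusters, sized)
    logger.info("deduplicate: %d sets -> %d representatives", len(collection), len(reduced))
    return reduced, clusters


def cluster_report(clusters: list[GeneSetCluster], collection: GeneSetCollection) -> pd.DataFrame:
    """Tabular cluster summary (cluster id, representative, members)."""
    rows = []
    for i, c in enumerate(sorted(clusters, key=lambda c: -len(c.members))):
        rows.append(
            {
                "cluster": i,
                "representative": c.representative,
                "n_members": len(c.members),
                "members": ",".join(c.members),
            }
        )
    return pd.DataFrame(rows)
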
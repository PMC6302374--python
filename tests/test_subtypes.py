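"""Subtype discovery: shifted Mann-Whitney tests, gsScore, embedding plumbing."""

import itertools

import numpy as np
import pandas as pd
import pytest

from gsae.subtypes import (
    NOISE,
    cluster_embedding,
    differential_supersets,
    embed_2d,
    gs_score,
    high_impact_gene_sets,
    overlap_sets,
    shifted_mww,
)


def mww_exact_oracle(x, y, mu=0.0):
    """One-sided P(U >= u_obs) for H1: x > y + mu, by full enumeration."""
    x = np.asarray(x, dtype=float) - mu
    y = np.asarray(y, dtype=float)

    def u_stat(a, b):
        return sum((ai > bj) + 0.5 * (ai == bj) for ai in a for bj in b)

    u_obs = u_stat(x, y)
    pooled = np.concatenate([x, y])
    m = len(x)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), m):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(idx)] = True
        if u_stat(pooled[mask], pooled[~mask]) >= u_obs:
            count += 1
        total += 1
    return count / total


class TestShiftedMww:
    def test_matches_exact_enumeration_oracle(self, rng):
        for _ in range(100):
            m, n = rng.integers(3, 8, size=2)
            x = rng.normal(1.0, 1.0, size=m)
            y = rng.normal(0.0, 1.0, size=n)
            mu = float(rng.uniform(0, 2))
            assert shifted_mww(x, y, mu=mu) == pytest.approx(mww_exact_oracle(x, y, mu))

    def test_shift_controls_stringency(self, rng):
        # group1 = rest + 5: detectable at shift 2, not at shift 9 (n = 20/20)
        rest = rng.normal(0, 1, size=20)
        g1 = rest + 5.0
        assert shifted_mww(g1, rest, mu=2.0) < 0.01
        assert shifted_mww(g1, rest, mu=9.0) > 0.5

    def test_all_tied_rejected(self):
        with pytest.raises(ValueError, match="tied"):
            shifted_mww(np.ones(5), np.ones(5))


class TestEmbed2d:
    def test_shape_and_determinism(self, rng):
        data = rng.normal(size=(50, 10))
        a = embed_2d(data, seed=4, perplexity=10)
        b = embed_2d(data, seed=4, perplexity=10)
        assert a.shape == (50, 2)
        np.testing.assert_array_equal(a, b)

    def test_separated_blobs_stay_separated(self, rng):
        blob1 = rng.normal(size=(40, 8))
        blob2 = rng.normal(size=(40, 8)) + 25.0
        coords = embed_2d(np.vstack([blob1, blob2]), seed=0, perplexity=15)
        c1, c2 = coords[:40], coords[40:]
        dist = np.linalg.norm(c1.mean(0) - c2.mean(0))
        radius = max(
            np.linalg.norm(c1 - c1.mean(0), axis=1).mean(),
            np.linalg.norm(c2 - c2.mean(0), axis=1).mean(),
        )
        assert dist > radius

    def test_perplexity_too_large_rejected(self, rng):
        with pytest.raises(ValueError, match="perplexity"):
            embed_2d(rng.normal(size=(30, 5)), perplexity=10)

    def test_pca_initialisation_path(self, rng):
        data = rng.normal(size=(40, 60))
        coords = embed_2d(data, seed=1, perplexity=10, pca_init_dim=20)
        assert coords.shape == (40, 2)


class TestClusterEmbedding:
    def test_two_blobs_found(self, rng):
        coords = np.vstack([
            rng.normal(size=(100, 2)),
            rng.normal(size=(100, 2)) + 15.0,
        ])
        labels = cluster_embedding(coords)
        assert len(set(labels) - {NOISE}) == 2

    def test_sparse_uniform_scatter_is_mostly_noise(self, rng):
        coords = rng.uniform(0, 1000, size=(60, 2))
        labels = cluster_embedding(coords, min_cluster_size=10)
        assert (labels == NOISE).mean() > 0.5

    def test_noise_excluded_from_differential_groups(self, rng):
        scores = rng.normal(size=(30, 3))
        labels = np.array([0] * 10 + [1] * 10 + [NOISE] * 10)
        scores[labels == NOISE] += 100.0  # would dominate if noise leaked in
        with_noise = differential_supersets(scores, labels, group1=0, mu=0.0)
        without = differential_supersets(scores[:20], labels[:20], group1=0, mu=0.0)
        assert [(r.index, r.direction, r.p_value) for r in with_noise] == [
            (r.index, r.direction, r.p_value) for r in without
        ]


class TestDifferentialSupersets:
    def test_identical_distributions_yield_nothing(self, rng):
        scores = np.tile(rng.normal(size=(40, 1)), (1, 5))
        labels = np.array([0, 1] * 20)
        assert differential_supersets(scores, labels, 0, mu=0.0) == []

    def test_planted_shift_detected_with_direction(self, rng):
        labels = np.array([0] * 25 + [1] * 25)
        scores = rng.normal(size=(50, 4))
        scores[labels == 1, 0] += 6.0   # up in group 1
        scores[labels == 1, 1] -= 6.0   # down in group 1
        results = differential_supersets(scores, labels, group1=1, mu=2.0)
        by_index = {r.index: r.direction for r in results}
        assert by_index == {0: "up", 1: "down"}

    def test_up_call_implies_larger_median(self, rng):
        labels = np.array([0] * 30 + [1] * 30)
        scores = rng.normal(size=(60, 6))
        scores[labels == 1, :3] += 3.0
        for r in differential_supersets(scores, labels, 1, mu=1.0):
            g1 = np.median(scores[labels == 1, r.index])
            g2 = np.median(scores[labels == 0, r.index])
            assert (g1 > g2) == (r.direction == "up")

    def test_constant_superset_skipped_with_warning(self, rng):
        scores = np.column_stack([np.ones(20), rng.normal(size=20)])
        labels = np.array([0, 1] * 10)
        with pytest.warns(UserWarning, match="tied"):
            differential_supersets(scores, labels, 0, mu=0.0)


class TestGsScore:
    def test_defining_identity(self):
        scores = np.array([[1.0], [1.0], [0.5], [0.5]])
        labels = np.array([1, 1, 0, 0])
        table = gs_score(scores, labels, 1, np.array([0.2]))
        assert table.loc[0, "gsScore"] == pytest.approx((1.0 - 0.5) * 0.2)

    def test_zero_weight_gives_zero_score(self, rng):
        scores = rng.normal(size=(20, 1)) + np.array([0, 1] * 10)[:, None]
        table = gs_score(scores, np.array([0, 1] * 10), 1, np.array([0.0]))
        assert table.loc[0, "gsScore"] == 0.0

    def test_equal_group_means_give_zero_score(self, rng):
        half = rng.normal(size=(10, 1))
        scores = np.abs(np.vstack([half, half]))
        labels = np.array([0] * 10 + [1] * 10)
        table = gs_score(scores, labels, 1, np.array([0.7]))
        assert table.loc[0, "gsScore"] == pytest.approx(0.0, abs=1e-12)

    def test_identity_holds_to_machine_precision(self, rng):
        scores = np.abs(rng.normal(size=(40, 8)))
        labels = np.array([0] * 22 + [1] * 18)
        w = rng.normal(size=8)
        table = gs_score(scores, labels, 1, w)
        recomputed = (table["mu1"] - table["mu2"]) * table["weight"]
        np.testing.assert_array_equal(table["gsScore"].to_numpy(), recomputed.to_numpy())

    def test_sorted_descending(self, rng):
        scores = np.abs(rng.normal(size=(30, 6)))
        labels = np.array([0, 1] * 15)
        table = gs_score(scores, labels, 1, rng.normal(size=6))
        assert (np.diff(table["gsScore"].to_numpy()) <= 0).all()


class TestHighImpactGeneSets:
    def _table(self, scores):
        return pd.DataFrame(
            {"gene_set": [f"S{i}" for i in range(len(scores))], "gsScore": scores}
        )

    def test_all_equal_scores_give_empty_selection(self):
        with pytest.warns(UserWarning, match="zero"):
            assert high_impact_gene_sets(self._table([0.3] * 6)) == []

    def test_outlier_selected_by_two_sd_rule(self):
        scores = [5.0, 0.1, -0.1, 0.2, 0.0, -0.2]
        table = self._table(scores)
        sd = np.std(scores, ddof=1)
        expected = [f"S{i}" for i, s in enumerate(scores) if s > 2 * sd]
        assert high_impact_gene_sets(table, "up") == expected == ["S0"]

    def test_down_direction_takes_left_tail(self):
        table = self._table([-5.0, 0.1, -0.1, 0.2, 0.0, -0.2])
        assert high_impact_gene_sets(table, "down") == ["S0"]

    def test_selection_shrinks_as_cutoff_grows(self, rng):
        table = self._table(list(rng.normal(size=30)))
        sizes = [len(high_impact_gene_sets(table, "up", k_sd=k)) for k in (0.5, 1.0, 2.0)]
        assert sizes == sorted(sizes, reverse=True)


class TestOverlapSets:
    def test_identical_lists_fully_overlap(self):
        regions = overlap_sets([["a", "b"], ["a", "b"]])
        assert regions[(1, 1)] == ["a", "b"]
        assert regions[(1, 0)] == [] and regions[(0, 1)] == []

    def test_disjoint_lists_share_nothing(self):
        regions = overlap_sets([["a"], ["b"]])
        assert regions[(1, 1)] == []

    def test_three_list_regions_match_enumeration(self, rng):
        lists = [list(rng.choice(list("abcdefghij"), size=6, replace=False)) for _ in range(3)]
        regions = overlap_sets(lists)
        for name in set().union(*map(set, lists)):
            pattern = tuple(int(name in l) for l in lists)
            assert name in regions[pattern]
        counts = sum(len(v) for v in regions.values())
        assert counts == len(set().union(*map(set, lists)))
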
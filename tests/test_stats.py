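"""Hierarchical bootstrap, Wilcoxon, cluster permutation, correlations, masks."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from fixenc.stats import (NestedSample, cluster_permutation, grid_adjacency,
                          hierarchical_bootstrap_p, mask_significant_features,
                          spearman_with_bonferroni, wilcoxon_signed_rank)
from fixenc.stats import _find_signed_clusters, _neighbor_lists, _t_maps


class TestNestedSample:
    def test_from_records_and_rectangular(self):
        records = [("p1", "s1", 0.1), ("p1", "s1", 0.2),
                   ("p1", "s2", 0.3), ("p1", "s2", 0.4),
                   ("p2", "s3", 0.5), ("p2", "s3", 0.6),
                   ("p2", "s4", 0.7), ("p2", "s4", 0.8)]
        sample = NestedSample.from_records(records)
        rect = sample.rectangular()
        assert rect.shape == (2, 2, 2)
        assert rect[0, 0, 1] == 0.2

    def test_ragged_returns_none(self):
        sample = NestedSample.from_records(
            [("p1", "s1", 0.1), ("p2", "s2", 0.2), ("p2", "s2", 0.3)])
        assert sample.rectangular() is None

    def test_validation(self):
        with pytest.raises(ValueError):
            NestedSample(data={})
        with pytest.raises(ValueError, match="non-finite"):
            NestedSample(data={"p": {"s": np.array([np.nan])}})


class TestHierarchicalBootstrap:
    def test_strong_positive_effect_small_p(self):
        rng = np.random.default_rng(0)
        records = [(p, f"{p}_{s}", 1.0 + rng.normal() * 0.1)
                   for p in range(6) for s in range(2) for _ in range(4)]
        p = hierarchical_bootstrap_p(NestedSample.from_records(records),
                                     n_boot=999, rng=np.random.default_rng(1))
        assert p == pytest.approx(1 / 1000)

    def test_negative_effect_large_p(self):
        rng = np.random.default_rng(2)
        records = [(p, f"{p}_{s}", -1.0 + rng.normal() * 0.1)
                   for p in range(6) for s in range(2) for _ in range(4)]
        p = hierarchical_bootstrap_p(NestedSample.from_records(records),
                                     n_boot=999, rng=np.random.default_rng(3))
        assert p == 1.0

    def test_ragged_path_agrees_on_strong_signal(self):
        # same records minus one block: forces the per-replicate python path
        rng = np.random.default_rng(4)
        records = [(p, f"{p}_{s}", 1.0 + rng.normal() * 0.1)
                   for p in range(6) for s in range(2) for _ in range(4)]
        p = hierarchical_bootstrap_p(NestedSample.from_records(records[:-1]),
                                     n_boot=499, rng=np.random.default_rng(5))
        assert p == pytest.approx(1 / 500)

    def test_add_one_smoothing_bounds(self):
        sample = NestedSample.from_records([("p", "s", 1.0), ("p", "s", 2.0)])
        p = hierarchical_bootstrap_p(sample, n_boot=100,
                                     rng=np.random.default_rng(6))
        assert 1 / 101 <= p <= 1.0


def brute_force_wilcoxon_p(diffs):
    """P(W+ >= observed) over all sign assignments of the ranked |d|."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    count = 0
    for signs in itertools.product([0, 1], repeat=len(ranks)):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if w >= w_obs - 1e-12:
            count += 1
    return count / 2 ** len(ranks)


class TestWilcoxon:
    def test_w_statistic_oracle(self):
        # diffs [+1, -2, +3]: ranks 1, 2, 3; positive ranks 1 + 3 = 4
        res = wilcoxon_signed_rank([0, 0, 0], [1, -2, 3])
        assert res.W == 4.0
        assert res.n == 3

    def test_41_all_positive_gives_861(self):
        after = np.arange(1, 42, dtype=float)
        res = wilcoxon_signed_rank(np.zeros(41), after)
        assert res.W == 861.0
        assert res.r_rank_biserial == 1.0

    def test_zeros_dropped(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 4.0, 5.0])
        assert res.n == 2

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0], [1.0])

    def test_exact_p_matches_scipy(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            d = rng.normal(size=9)
            res = wilcoxon_signed_rank(np.zeros(9), d)
            expected = sps.wilcoxon(d, alternative="greater",
                                    mode="exact").pvalue
            assert res.p == pytest.approx(expected)

    def test_exact_p_matches_brute_force_with_ties(self):
        d = [1.0, -1.0, 2.0, 2.0, -3.0, 4.0]
        res = wilcoxon_signed_rank(np.zeros(6), d)
        assert res.p == pytest.approx(brute_force_wilcoxon_p(d))

    def test_normal_approx_reasonable(self):
        rng = np.random.default_rng(8)
        d = rng.normal(0.8, 1.0, size=30)
        res = wilcoxon_signed_rank(np.zeros(30), d)
        expected = sps.wilcoxon(d, alternative="greater",
                                mode="approx", correction=True).pvalue
        assert res.p == pytest.approx(expected, rel=0.05)

    def test_two_sided_doubles(self):
        d = [1.0, 2.0, 3.0, -0.5]
        one = wilcoxon_signed_rank(np.zeros(4), d, one_sided=True)
        two = wilcoxon_signed_rank(np.zeros(4), d, one_sided=False)
        assert two.p == pytest.approx(min(1.0, 2 * one.p))

    @given(st.lists(st.sampled_from([-3.0, -2.0, -1.0, 1.0, 2.0, 3.0]),
                    min_size=1, max_size=8))
    def test_exact_equals_enumeration(self, diffs):
        res = wilcoxon_signed_rank(np.zeros(len(diffs)), diffs)
        assert res.p == pytest.approx(brute_force_wilcoxon_p(diffs))


class TestAdjacency:
    def test_grid_2x2(self):
        adj = grid_adjacency(2, 2)
        assert adj.sum() == 8            # 4 undirected edges
        assert adj[0, 1] and adj[0, 2] and not adj[0, 3]

    def test_edge_list_equivalent(self):
        adj = grid_adjacency(2, 2)
        edges = [(i, j) for i in range(4) for j in range(i + 1, 4) if adj[i, j]]
        assert _neighbor_lists(edges, 4) == _neighbor_lists(adj, 4)

    def test_disconnected_warns(self):
        with pytest.warns(UserWarning, match="disconnected"):
            _neighbor_lists(np.zeros((3, 3), dtype=bool), 3)


class TestClusterFinding:
    def test_t_maps_match_scipy(self):
        rng = np.random.default_rng(9)
        data = rng.normal(size=(8, 12))
        t = _t_maps(data, np.ones((1, 8)))[0]
        expected = sps.ttest_1samp(data, 0.0, axis=0).statistic
        assert np.allclose(t, expected)

    def test_signed_clusters_split_by_sign_and_space(self):
        t = np.zeros((4, 6))
        t[0, 1:4] = 3.0          # cluster A: channel 0, lags 1-3
        t[1, 1:4] = 3.0          # adjacent channel joins A (grid 2x2: 0-1)
        t[3, 1:4] = -3.0         # opposite sign, separate cluster
        t[0, 5] = 3.0            # temporally isolated point
        neighbors = _neighbor_lists(grid_adjacency(2, 2), 4)
        clusters = _find_signed_clusters(t, 2.5, neighbors)
        masses = sorted(m for _, m in clusters)
        assert masses == [-9.0, 3.0, 18.0]


class TestClusterPermutation:
    def test_planted_effect_minimal_p(self):
        rng = np.random.default_rng(10)
        trfs = rng.normal(size=(12, 4, 20)) * 0.1
        trfs[:, :2, 5:10] += 2.0          # strong consistent effect
        result = cluster_permutation(trfs, grid_adjacency(2, 2),
                                     n_perm=200, rng=np.random.default_rng(11))
        top = result.clusters[0]
        assert top.p == pytest.approx(1 / 201)
        points = {(c, l) for c, l in top.members}
        assert {(c, l) for c in range(2) for l in range(5, 10)} <= points

    def test_pure_noise_rarely_significant(self):
        rng = np.random.default_rng(12)
        trfs = rng.normal(size=(10, 4, 15))
        result = cluster_permutation(trfs, grid_adjacency(2, 2), n_perm=200,
                                     rng=np.random.default_rng(13))
        assert all(c.p > 0.05 for c in result.clusters) or not result.clusters

    def test_needs_two_sessions(self):
        with pytest.raises(ValueError):
            cluster_permutation(np.zeros((1, 4, 5)), grid_adjacency(2, 2))


class TestSpearman:
    def test_oracle(self):
        rho, p = spearman_with_bonferroni([1, 2, 3], [3, 1, 2])
        assert rho == pytest.approx(-0.5)

    def test_bonferroni_caps_at_one(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        rho, p1 = spearman_with_bonferroni(x, y, n_tests=1)
        _, p7 = spearman_with_bonferroni(x, y, n_tests=7)
        assert p7 == min(1.0, 7 * p1)

    def test_constant_input_raises(self):
        with pytest.raises(ValueError):
            spearman_with_bonferroni([1, 1, 1], [1, 2, 3])


class TestMasking:
    def test_joint_rule(self):
        delta = np.array([1e-3, 1e-3, 1e-6, 1e-3])
        p = np.array([0.01, 0.2, 0.01, 0.049])
        mask = mask_significant_features(delta, p, dr_min=2e-5, alpha=0.05)
        assert mask.tolist() == [True, False, False, True]

    def test_trf_threshold_stricter(self):
        delta = np.array([2.5e-5])
        p = np.array([0.001])
        assert mask_significant_features(delta, p, dr_min=2e-5)[0]
        assert not mask_significant_features(delta, p, dr_min=3e-5)[0]

    def test_pandas_alignment_checked(self):
        a = pd.Series([1e-3], index=["x"])
        b = pd.Series([0.01], index=["y"])
        with pytest.raises(ValueError, match="misaligned"):
            mask_significant_features(a, b)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            mask_significant_features(np.zeros(3), np.zeros(4))
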
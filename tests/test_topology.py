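"""Density thresholding, graph metrics against brute-force oracles, AUC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iscn.network import SimilarityNetwork
from iscn.topology import (
    BinaryNetwork,
    _edge_count,
    clustering_coefficient_adj,
    global_efficiency_adj,
    global_metrics,
    maslov_sneppen_rewire,
    metric_auc,
    modularity_adj,
    nodal_metrics,
    select_threshold_range,
    small_worldness_adj,
    threshold_binarize,
)
from oracles import (
    brute_clustering,
    brute_global_efficiency,
    brute_max_modularity,
    brute_path_length,
)


def _similarity(matrix, ids=None):
    m = np.asarray(matrix, dtype=float)
    return SimilarityNetwork("s", ids or list(range(1, m.shape[0] + 1)), m)


def _random_similarity(rng, r):
    w = rng.uniform(0.01, 1.0, (r, r))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0)
    return _similarity(w)


def _bn(adj):
    a = np.asarray(adj, dtype=np.uint8)
    return BinaryNetwork(a, 50.0, list(range(1, a.shape[0] + 1)))


def complete(n):
    a = np.ones((n, n), dtype=np.uint8)
    np.fill_diagonal(a, 0)
    return a


class TestThresholdBinarize:
    def test_edge_count_r5_k40(self, rng):
        net = _random_similarity(rng, 5)
        assert threshold_binarize(net, 40).n_edges == 4

    def test_edge_count_246_region_atlas(self):
        # 246 regions at K=12: round(0.12 * 30135) = 3616 edges
        assert _edge_count(246, 12) == 3616

    def test_tie_break_is_deterministic_index_order(self):
        w = np.full((4, 4), 0.5)
        np.fill_diagonal(w, 0)
        net = _similarity(w)
        b = threshold_binarize(net, 50)
        assert b.n_edges == 3
        i, j = np.nonzero(np.triu(b.adjacency, 1))
        assert list(zip(i, j)) == [(0, 1), (0, 2), (0, 3)]

    def test_k_out_of_range(self, rng):
        net = _random_similarity(rng, 5)
        for k in (0, 100, -3):
            with pytest.raises(ValueError):
                threshold_binarize(net, k)

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 10_000), st.integers(5, 60))
    def test_edge_count_identical_across_subjects(self, seed, k):
        rng = np.random.default_rng(seed)
        n1 = threshold_binarize(_random_similarity(rng, 12), k)
        n2 = threshold_binarize(_random_similarity(rng, 12), k)
        assert n1.n_edges == n2.n_edges == _edge_count(12, k)

    def test_retained_edges_nest_with_density(self, rng):
        net = _random_similarity(rng, 15)
        prev = threshold_binarize(net, 10).adjacency
        for k in (20, 30, 40):
            cur = threshold_binarize(net, k).adjacency
            assert np.all(cur >= prev)  # edges only added as K grows
            prev = cur


class TestGlobalMetrics:
    def test_complete_graph(self):
        g = global_metrics(_bn(complete(5)), n_random=5, seed=0)
        assert g.global_efficiency == 1.0
        assert g.clustering_coefficient == 1.0
        assert np.isnan(g.assortativity)  # regular graph: undefined

    def test_path_graph_efficiency(self):
        a = np.zeros((3, 3), dtype=np.uint8)
        a[0, 1] = a[1, 0] = a[1, 2] = a[2, 1] = 1
        assert global_efficiency_adj(a) == pytest.approx((1 + 1 + 0.5) / 3)

    def test_two_triangles_modularity_half(self):
        a = np.zeros((6, 6), dtype=np.uint8)
        for block in ([0, 1, 2], [3, 4, 5]):
            for i in block:
                for j in block:
                    if i != j:
                        a[i, j] = 1
        assert modularity_adj(a, seed=0) == pytest.approx(0.5)
        assert brute_max_modularity(a) == pytest.approx(0.5)
        assert global_efficiency_adj(a) < 1.0  # unreachable pairs contribute 0

    def test_zero_edges_error(self):
        with pytest.raises(ValueError, match="zero edges"):
            global_metrics(_bn(np.zeros((4, 4))))

    def test_efficiency_nondecreasing_in_density(self, rng):
        net = _random_similarity(rng, 20)
        effs = [global_efficiency_adj(threshold_binarize(net, k).adjacency) for k in range(10, 60, 5)]
        assert all(b >= a for a, b in zip(effs, effs[1:]))


class TestNodalMetrics:
    def test_star_graph(self):
        a = np.zeros((5, 5), dtype=np.uint8)
        a[0, 1:] = a[1:, 0] = 1
        nm = nodal_metrics(_bn(a))
        assert nm.degree[0] == 4 and np.all(nm.degree[1:] == 1)
        assert nm.betweenness[0] == pytest.approx(1.0)
        assert np.all(nm.betweenness[1:] == 0)
        assert nm.eigenvector[0] == pytest.approx(1.0)

    def test_cycle_graph_vertex_transitive(self):
        n = 6
        a = np.zeros((n, n), dtype=np.uint8)
        for i in range(n):
            a[i, (i + 1) % n] = a[(i + 1) % n, i] = 1
        nm = nodal_metrics(_bn(a))
        assert np.all(nm.degree == 2)
        assert np.allclose(nm.betweenness, nm.betweenness[0])
        assert np.allclose(nm.eigenvector, 1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_betweenness_matches_path_enumeration(self, seed):
        from oracles import brute_betweenness

        rng = np.random.default_rng(seed)
        a = (rng.random((12, 12)) < 0.3).astype(np.uint8)
        a = np.triu(a, 1)
        a = a + a.T
        if a.sum() == 0:
            pytest.skip("empty draw")
        nm = nodal_metrics(_bn(a))
        np.testing.assert_allclose(nm.betweenness, brute_betweenness(a), atol=1e-10)


class TestRewiring:
    def test_degree_sequence_preserved(self, rng):
        a = (rng.random((20, 20)) < 0.3).astype(np.uint8)
        a = np.triu(a, 1)
        a = a + a.T
        surr = maslov_sneppen_rewire(a, seed=4)
        assert np.array_equal(surr.sum(axis=1), a.sum(axis=1))
        assert np.array_equal(surr, surr.T)
        assert np.all(np.diag(surr) == 0)

    def test_rewire_actually_changes_graph(self, rng):
        a = (rng.random((30, 30)) < 0.2).astype(np.uint8)
        a = np.triu(a, 1)
        a = a + a.T
        assert not np.array_equal(maslov_sneppen_rewire(a, seed=1), a)

    def test_sigma_deterministic_given_seed(self, rng):
        a = (rng.random((25, 25)) < 0.25).astype(np.uint8)
        a = np.triu(a, 1)
        a = a + a.T
        s1 = small_worldness_adj(a, n_random=10, seed=42)
        s2 = small_worldness_adj(a, n_random=10, seed=42)
        assert s1 == s2

    def test_sigma_parts_consistent(self, rng):
        a = (rng.random((25, 25)) < 0.25).astype(np.uint8)
        a = np.triu(a, 1)
        a = a + a.T
        sigma, parts = small_worldness_adj(a, n_random=8, seed=3, return_parts=True)
        expected = (parts["C"] / parts["C_rand"]) / (parts["L"] / parts["L_rand"])
        assert sigma == pytest.approx(expected)
        assert parts["C"] == pytest.approx(brute_clustering(a))
        assert parts["L"] == pytest.approx(brute_path_length(a))


class TestSelectThresholdRange:
    def test_deterministic_and_valid(self, small_cohort):
        nets = small_cohort["networks"]
        r1 = select_threshold_range(nets, seed=5, n_random=8)
        r2 = select_threshold_range(nets, seed=5, n_random=8)
        assert r1 == r2
        assert r1[0] <= r1[1]

    def test_dense_similarity_connects_at_small_k(self, rng):
        # distinct dense weights: the connectedness scan succeeds early,
        # well below half density
        from iscn.topology import is_connected_adj

        for _ in range(3):
            net = _random_similarity(rng, 12)
            k_min = next(
                k for k in range(1, 100)
                if is_connected_adj(threshold_binarize(net, k).adjacency)
            )
            assert k_min <= 40
            assert is_connected_adj(threshold_binarize(net, k_min).adjacency)

    def test_empty_cohort_errors(self):
        with pytest.raises(ValueError, match="empty"):
            select_threshold_range([])


class TestAuc:
    def test_constant_metric_over_fixed_range(self):
        ks = list(range(12, 40))  # 12..39 inclusive, span 27
        assert metric_auc([3.0] * len(ks)) == pytest.approx(27 * 3.0)

    def test_linear_metric_exact(self):
        ks = np.arange(10, 31)
        vals = 0.5 * ks + 2
        exact = 0.25 * (30**2 - 10**2) + 2 * 20  # integral of the line
        assert metric_auc(vals) == pytest.approx(exact)

    def test_random_curve_matches_resummation_oracle(self, rng):
        vals = rng.random(15)
        oracle = sum((vals[i] + vals[i + 1]) / 2 for i in range(14))
        assert metric_auc(vals) == pytest.approx(oracle)

    def test_single_threshold_errors(self):
        with pytest.raises(ValueError):
            metric_auc([1.0])


def test_global_metrics_match_oracles_on_random_graphs(rng):
    """Efficiency and clustering equal brute-force enumeration on random
    10-node graphs (the exhaustive <= 8-node sweep lives in acceptance)."""
    for _ in range(10):
        a = (rng.random((10, 10)) < 0.35).astype(np.uint8)
        a = np.triu(a, 1)
        a = a + a.T
        if a.sum() == 0:
            continue
        assert global_efficiency_adj(a) == pytest.approx(brute_global_efficiency(a))
        assert clustering_coefficient_adj(a) == pytest.approx(brute_clustering(a))
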
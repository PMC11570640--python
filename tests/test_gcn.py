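"""Graph-convolution core: oracles for conv, scoring, sparsemax,
structure learning and readout."""

import numpy as np
import pytest

from moodgraph import gcn
from moodgraph.graphs import build_chain_adjacency

from conftest import random_connected_graph


def gcn_loop_oracle(h, a, w):
    """Per-node double-loop normalized aggregation with self-loops."""
    n = h.shape[0]
    a_hat = a + np.eye(n)
    deg = a_hat.sum(axis=1)
    out = np.zeros((n, w.shape[1]))
    for v in range(n):
        acc = np.zeros(h.shape[1])
        for u in range(n):
            if a_hat[v, u] != 0:
                acc += a_hat[v, u] / np.sqrt(deg[v] * deg[u]) * h[u]
        out[v] = acc @ w
    return np.maximum(out, 0.0)


def info_score_loop_oracle(h, a):
    n = h.shape[0]
    scores = np.zeros(n)
    for v in range(n):
        deg = a[v].sum()
        nb = (a[v] @ h) / deg if deg > 0 else np.zeros(h.shape[1])
        scores[v] = np.abs(h[v] - nb).sum()
    return scores


def simplex_projection_bisection(z, tol=1e-12):
    """Independent oracle: find tau with sum(max(z - tau, 0)) = 1 by
    bisection (the KKT condition of the Euclidean simplex projection)."""
    lo, hi = z.min() - 1.0, z.max()
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        s = np.maximum(z - mid, 0.0).sum()
        if s > 1.0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return np.maximum(z - 0.5 * (lo + hi), 0.0)


class TestGcnForward:
    def test_single_node_reduces_to_dense_layer(self):
        h = np.array([[1.0, -2.0]])
        w = np.array([[1.0], [0.5]])
        out = gcn.gcn_forward(h, np.zeros((1, 1)), w)
        np.testing.assert_allclose(out, np.maximum(h @ w, 0.0))

    def test_two_node_regular_graph_preserves_constant(self):
        h = np.array([[1.0], [1.0]])
        a = np.array([[0.0, 1.0], [1.0, 0.0]])
        out = gcn.gcn_forward(h, a, np.array([[1.0]]))
        np.testing.assert_allclose(out, [[1.0], [1.0]])

    def test_matches_loop_oracle_on_random_graphs(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(2, 11))
            h = rng.normal(size=(n, 3))
            a = random_connected_graph(rng, n)
            w = rng.normal(size=(3, 2))
            np.testing.assert_allclose(gcn.gcn_forward(h, a, w),
                                       gcn_loop_oracle(h, a, w), atol=1e-10)

    def test_nan_input_rejected(self):
        with pytest.raises(ValueError):
            gcn.gcn_forward(np.array([[np.nan]]), np.zeros((1, 1)),
                            np.ones((1, 1)))


class TestInfoScore:
    def test_identical_features_on_regular_graph_score_zero(self):
        h = np.tile([[2.0, -1.0]], (4, 1))
        a = 1.0 - np.eye(4)  # complete graph is regular
        np.testing.assert_allclose(gcn.info_score(h, a), 0.0, atol=1e-12)

    def test_two_node_hand_computation(self):
        h = np.array([[0.0], [2.0]])
        a = np.array([[0.0, 1.0], [1.0, 0.0]])
        np.testing.assert_allclose(gcn.info_score(h, a), [2.0, 2.0])

    def test_isolated_node_scores_own_l1_norm(self):
        h = np.array([[3.0, -4.0]])
        assert gcn.info_score(h, np.zeros((1, 1)))[0] == pytest.approx(7.0)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            n = int(rng.integers(2, 11))
            h = rng.normal(size=(n, 4))
            a = random_connected_graph(rng, n)
            np.testing.assert_allclose(gcn.info_score(h, a),
                                       info_score_loop_oracle(h, a), atol=1e-12)


class TestTopKAndPool:
    def test_topk_examples(self):
        np.testing.assert_array_equal(
            gcn.top_k_select(np.array([3.0, 1.0, 2.0]), 2 / 3), [0, 2])
        np.testing.assert_array_equal(
            gcn.top_k_select(np.array([3.0, 1.0, 2.0]), 1.0), [0, 1, 2])
        np.testing.assert_array_equal(
            gcn.top_k_select(np.array([1.0, 1.0, 1.0]), 1 / 3), [0])

    def test_pool_identity_and_disconnection(self):
        h = np.arange(6.0).reshape(3, 2)
        a = build_chain_adjacency(3).astype(float)
        hp, ap = gcn.pool(h, a, np.array([0, 1, 2]))
        np.testing.assert_array_equal(hp, h)
        np.testing.assert_array_equal(ap, a)
        # dropping the middle node of a chain disconnects the ends
        hp, ap = gcn.pool(h, a, np.array([0, 2]))
        assert ap.sum() == 0

    def test_pool_single_node(self):
        h = np.arange(6.0).reshape(3, 2)
        a = build_chain_adjacency(3).astype(float)
        hp, ap = gcn.pool(h, a, np.array([1]))
        assert hp.shape == (1, 2) and ap.shape == (1, 1) and ap[0, 0] == 0

    def test_pool_out_of_range(self):
        with pytest.raises(IndexError):
            gcn.pool(np.zeros((2, 1)), np.zeros((2, 2)), np.array([3]))


class TestSparsemax:
    def test_uniform_and_one_hot(self):
        np.testing.assert_allclose(gcn.sparsemax(np.zeros(2)), [0.5, 0.5])
        np.testing.assert_allclose(gcn.sparsemax(np.array([1.0, 0.0])),
                                   [1.0, 0.0])

    def test_matches_bisection_oracle_on_random_vectors(self):
        rng = np.random.default_rng(9)
        for _ in range(300):
            n = int(rng.integers(1, 17))
            z = rng.normal(scale=rng.uniform(0.1, 5.0), size=n)
            p = gcn.sparsemax(z)
            assert p.sum() == pytest.approx(1.0, abs=1e-12)
            assert p.min() >= 0.0
            np.testing.assert_allclose(p, simplex_projection_bisection(z),
                                       atol=1e-8)

    def test_produces_exact_zeros_on_spread_input(self):
        p = gcn.sparsemax(np.array([5.0, 0.0, -5.0]))
        assert (p == 0.0).sum() >= 1

    def test_rejects_empty_and_nonfinite(self):
        with pytest.raises(ValueError):
            gcn.sparsemax(np.array([]))
        with pytest.raises(ValueError):
            gcn.sparsemax(np.array([np.inf, 0.0]))


class TestStructureLearning:
    def test_rows_are_distributions(self):
        rng = np.random.default_rng(10)
        h = rng.normal(size=(6, 3))
        a = random_connected_graph(rng, 6)
        s = gcn.structure_learning(h, a, rng.normal(size=6))
        np.testing.assert_allclose(s.sum(axis=1), 1.0, atol=1e-12)
        assert s.min() >= 0.0

    def test_large_lambda_concentrates_on_existing_edges(self):
        rng = np.random.default_rng(11)
        h = rng.normal(size=(5, 2))
        a = build_chain_adjacency(5).astype(float)
        s = gcn.structure_learning(h, a, np.zeros(4), lam=1e6)
        for p in range(5):
            edges = a[p] > 0
            np.testing.assert_allclose(s[p, ~edges], 0.0, atol=1e-9)
            np.testing.assert_allclose(s[p, edges], 1.0 / edges.sum(),
                                       atol=1e-6)

    def test_single_node_gives_unit_simplex(self):
        s = gcn.structure_learning(np.array([[1.0, 2.0]]), np.zeros((1, 1)),
                                   np.zeros(4))
        np.testing.assert_allclose(s, [[1.0]])

    def test_identical_features_no_edges_gives_uniform_rows(self):
        h = np.tile([[1.0, -1.0]], (4, 1))
        s = gcn.structure_learning(h, np.zeros((4, 4)), np.ones(4))
        np.testing.assert_allclose(s, 0.25)

    def test_attention_vector_length_checked(self):
        with pytest.raises(ValueError):
            gcn.structure_learning(np.zeros((2, 3)), np.zeros((2, 2)),
                                   np.zeros(4))


class TestReadoutAndStack:
    def test_single_node_readout(self):
        h = np.array([[1.0, -2.0]])
        np.testing.assert_allclose(gcn.readout(h), [1.0, -2.0, 1.0, -2.0])

    def test_hand_computed_readout(self):
        h = np.array([[1.0, 0.0], [3.0, 2.0]])
        np.testing.assert_allclose(gcn.readout(h), [2.0, 1.0, 3.0, 2.0])

    def test_readout_permutation_invariant_and_zero(self):
        rng = np.random.default_rng(12)
        h = rng.normal(size=(6, 3))
        np.testing.assert_allclose(gcn.readout(h),
                                   gcn.readout(h[rng.permutation(6)]))
        np.testing.assert_allclose(gcn.readout(np.zeros((4, 2))), 0.0)

    def _units(self, rng, d_in, d, k):
        units = []
        for i in range(k):
            units.append(gcn.UnitParams(
                conv_weight=rng.normal(size=(d_in if i == 0 else d, d)),
                attention_vector=rng.normal(size=2 * d)))
        return units

    def test_depth_zero_reads_out_input(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=(5, 3))
        a = random_connected_graph(rng, 5)
        np.testing.assert_allclose(gcn.multi_gcn_forward(x, a, []),
                                   gcn.readout(x))

    def test_single_node_single_unit(self):
        rng = np.random.default_rng(14)
        units = self._units(rng, 3, 2, 1)
        x = rng.normal(size=(1, 3))
        f_g, trace = gcn.multi_gcn_forward(x, np.zeros((1, 1)), units,
                                           return_trace=True)
        np.testing.assert_allclose(f_g, trace[0]["readout"])

    @pytest.mark.parametrize("n", [4, 9, 16])
    def test_embedding_length_is_2d_regardless_of_n(self, n):
        rng = np.random.default_rng(15)
        units = self._units(rng, 3, 5, 3)
        x = rng.normal(size=(n, 3))
        a = random_connected_graph(rng, n)
        assert gcn.multi_gcn_forward(x, a, units).shape == (10,)

    def test_pooling_strictly_decreases_node_count(self):
        rng = np.random.default_rng(16)
        units = self._units(rng, 3, 4, 3)
        x = rng.normal(size=(11, 3))
        a = random_connected_graph(rng, 11)
        _, trace = gcn.multi_gcn_forward(x, a, units, return_trace=True)
        sizes = [t["h"].shape[0] for t in trace]
        assert sizes == [6, 3, 2]

    def test_end_to_end_permutation_invariance(self):
        rng = np.random.default_rng(17)
        units = self._units(rng, 4, 3, 3)
        x = rng.normal(size=(10, 4))
        a = random_connected_graph(rng, 10)
        f = gcn.multi_gcn_forward(x, a, units)
        for _ in range(5):
            perm = rng.permutation(10)
            f_p = gcn.multi_gcn_forward(x[perm], a[np.ix_(perm, perm)], units)
            np.testing.assert_allclose(f_p, f, atol=1e-9)

    def test_sparsemax_rows_statistically_sparse(self):
        rng = np.random.default_rng(18)
        zero_counts = 0
        rows = 0
        for _ in range(100):
            z = rng.normal(scale=3.0, size=8)
            p = gcn.sparsemax(z)
            rows += 1
            zero_counts += (p == 0).sum() >= 1
        assert zero_counts / rows > 0.95
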
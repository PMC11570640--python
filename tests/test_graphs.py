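"""Montage graphs: local k-NN, symmetric pairs, chain, combination, I/O."""

import numpy as np
import pytest

from moodgraph import graphs as gr


def _montage(coords, hemis=None, labels=None):
    n = len(coords)
    return gr.ElectrodeMontage(
        labels=labels or [f"C{i}" for i in range(n)],
        coords=np.asarray(coords, dtype=float),
        hemisphere=hemis or ["midline"] * n,
    )


class TestLocalAdjacency:
    def test_three_collinear_nodes_k1(self):
        m = _montage([(0, 0), (1, 0), (2, 0)])
        a = gr.build_local_adjacency(m, k=1)
        expected = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
        np.testing.assert_array_equal(a, expected)

    def test_k_equals_n_minus_one_gives_complete_graph(self):
        rng = np.random.default_rng(0)
        m = _montage(rng.normal(size=(6, 2)))
        a = gr.build_local_adjacency(m, k=5)
        np.testing.assert_array_equal(a, 1 - np.eye(6, dtype=int))

    def test_unit_square_k2_links_sides_not_diagonal(self):
        m = _montage([(0, 0), (1, 0), (1, 1), (0, 1)])
        a = gr.build_local_adjacency(m, k=2)
        assert a[0, 2] == 0 and a[1, 3] == 0  # diagonals excluded
        for i, j in [(0, 1), (1, 2), (2, 3), (3, 0)]:
            assert a[i, j] == 1

    @pytest.mark.parametrize("k", [0, -1, 5])
    def test_invalid_k_rejected(self, k):
        m = _montage([(0, 0), (1, 0), (2, 0), (3, 0), (4, 0)])
        with pytest.raises(ValueError):
            gr.build_local_adjacency(m, k=k)

    def test_matches_bruteforce_knn_oracle_on_random_montages(self):
        rng = np.random.default_rng(42)
        for trial in range(20):
            n = int(rng.integers(4, 33))
            k = int(rng.integers(1, n))
            coords = rng.normal(size=(n, 2))
            m = _montage(coords)
            a = gr.build_local_adjacency(m, k=k)
            oracle = np.zeros((n, n), dtype=int)
            for i in range(n):
                d = np.linalg.norm(coords - coords[i], axis=1)
                d[i] = np.inf
                nearest = np.argsort(d, kind="stable")[:k]
                oracle[i, nearest] = 1
            oracle = np.maximum(oracle, oracle.T)
            np.testing.assert_array_equal(a, oracle)
            gr.validate_adjacency(a)

    def test_duplicate_coordinates_break_ties_to_lower_index(self):
        m = _montage([(0, 0), (1, 0), (1, 0), (1, 0)])
        a = gr.build_local_adjacency(m, k=1)
        # node 0 is equidistant from 1, 2, 3; lower index (1) wins
        assert a[0, 1] == 1 and a[0, 2] == 0 and a[0, 3] == 0


class TestSymmetricAdjacency:
    def _hemi_montage(self):
        return _montage(
            [(-1, 1), (-1, 0), (-2, 0), (0, 1), (1, 0), (1, 1)],
            hemis=["left", "left", "left", "midline", "right", "right"],
            labels=["F3", "C3", "T3", "Cz", "F4", "C4"],
        )

    def test_empty_pairs_gives_zero_matrix(self):
        a = gr.build_symmetric_adjacency(self._hemi_montage(), [])
        assert a.sum() == 0

    def test_single_pair_sets_both_entries(self):
        m = self._hemi_montage()
        a = gr.build_symmetric_adjacency(m, [("F3", "F4")])
        i, j = m.index_of("F3"), m.index_of("F4")
        assert a[i, j] == 1 and a[j, i] == 1 and a.sum() == 2

    def test_pair_count_matches_nonzeros(self):
        import moodgraph as mg

        m = mg.generate_montage(128)
        pairs = gr.default_symmetric_pairs(m)[:10]
        a = gr.build_symmetric_adjacency(m, pairs)
        assert a.sum() == 20  # 2 entries per pair

    def test_unknown_label_named_in_error(self):
        with pytest.raises(KeyError, match="XX"):
            gr.build_symmetric_adjacency(self._hemi_montage(), [("XX", "F4")])

    def test_same_hemisphere_pair_rejected(self):
        with pytest.raises(ValueError, match="left"):
            gr.build_symmetric_adjacency(self._hemi_montage(), [("F3", "C3")])


class TestCombineAndChain:
    def test_disjoint_union_and_overlap_clipping(self):
        a = np.zeros((3, 3), dtype=int)
        b = np.zeros((3, 3), dtype=int)
        a[0, 1] = a[1, 0] = 1
        b[1, 2] = b[2, 1] = 1
        b[0, 1] = b[1, 0] = 1  # overlap with a
        c = gr.combine_adjacency(a, b)
        assert c.max() == 1 and c[0, 1] == 1 and c[1, 2] == 1
        np.testing.assert_array_equal(gr.combine_adjacency(a, np.zeros_like(a)), a)
        np.testing.assert_array_equal(gr.combine_adjacency(a, b),
                                      gr.combine_adjacency(b, a))

    def test_combine_shape_mismatch(self):
        with pytest.raises(ValueError):
            gr.combine_adjacency(np.zeros((3, 3)), np.zeros((4, 4)))

    def test_chain_n3(self):
        a = gr.build_chain_adjacency(3)
        expected = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
        np.testing.assert_array_equal(a, expected)

    def test_chain_n1_is_zero(self):
        assert gr.build_chain_adjacency(1).sum() == 0

    @pytest.mark.parametrize("n", list(range(1, 65)))
    def test_chain_has_2n_minus_2_nonzeros_off_tridiagonal(self, n):
        a = gr.build_chain_adjacency(n)
        assert a.sum() == 2 * (n - 1)
        i, j = np.nonzero(a)
        assert np.all(np.abs(i - j) == 1)

    def test_chain_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            gr.build_chain_adjacency(0)


class TestMontageValidation:
    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError):
            _montage([(0, 0), (1, 0)], labels=["A", "A"])

    def test_nonfinite_coords_rejected(self):
        with pytest.raises(ValueError):
            _montage([(0, 0), (np.nan, 0)])


class TestIO:
    def test_montage_roundtrip(self, tmp_path, montage16):
        path = tmp_path / "montage.csv"
        gr.write_montage(montage16, path)
        back = gr.read_montage(path)
        assert back.labels == montage16.labels
        np.testing.assert_allclose(back.coords, montage16.coords)
        assert back.hemisphere == montage16.hemisphere

    def test_pairs_roundtrip(self, tmp_path, montage16):
        pairs = gr.default_symmetric_pairs(montage16)
        path = tmp_path / "pairs.csv"
        gr.write_symmetric_pairs(pairs, path)
        assert gr.read_symmetric_pairs(path) == pairs

    def test_adjacency_roundtrip_lossless(self, tmp_path, montage16):
        a = gr.build_local_adjacency(montage16, k=3)
        path = tmp_path / "adj.tsv"
        dense = tmp_path / "adj.csv"
        gr.write_adjacency(a, path, dense_path=dense)
        back = gr.read_adjacency(path, n=a.shape[0])
        np.testing.assert_array_equal(back, a)
        np.testing.assert_array_equal(np.loadtxt(dense, delimiter=","), a)


def test_default_symmetric_pairs_mirror_property(montage16):
    pairs = gr.default_symmetric_pairs(montage16)
    assert pairs, "mirrored montage must produce symmetric pairs"
    for left, right in pairs:
        i, j = montage16.index_of(left), montage16.index_of(right)
        assert montage16.hemisphere[i] == "left"
        assert montage16.hemisphere[j] == "right"
        # ring montage is exactly mirrored, so the match is exact
        np.testing.assert_allclose(montage16.coords[i] * [-1, 1],
                                   montage16.coords[j], atol=1e-9)
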
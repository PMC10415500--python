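"""Pattern graphs, effective resistances, RDHs and scalar features."""

import networkx as nx
import numpy as np
import pytest

from turingfit import (
    calibrate_rmax,
    connected_components_feature,
    max_concentration,
    pattern_graph,
    rdh,
    resistance_matrix,
)
from turingfit.features import (
    collect_resistance_values,
    pattern_rdh,
    rdh_from_values,
    torus_offsets,
)


def random_connected_adjacency(rng, n=6):
    """Random weighted adjacency of a connected graph (cycle + chords)."""
    A = np.zeros((n, n))
    for i in range(n):
        A[i, (i + 1) % n] = A[(i + 1) % n, i] = rng.uniform(0.2, 2.0)
    for _ in range(n):
        i, j = rng.integers(0, n, size=2)
        if i != j:
            w = rng.uniform(0.2, 2.0)
            A[i, j] = A[j, i] = w
    return A


class TestPatternGraph:
    def test_constant_field_all_unit_weights(self):
        g = pattern_graph(np.full((6, 6), 2.5))
        assert np.all(g.w_right == 1.0) and np.all(g.w_down == 1.0)

    def test_checkerboard_all_interface_weights(self):
        n = 6
        board = np.indices((n, n)).sum(axis=0) % 2
        g = pattern_graph(board.astype(float), eps_w=0.01)
        assert np.all(g.w_right == 0.01) and np.all(g.w_down == 0.01)

    def test_half_and_half_interface_edges(self):
        """Left half 2, right half 0: only the two vertical interfaces
        (middle and wrap-around) cross the mean."""
        f = np.zeros((4, 4))
        f[:, :2] = 2.0
        g = pattern_graph(f, eps_w=0.5)
        assert np.all(g.w_down == 1.0)
        expected_right = np.ones((4, 4))
        expected_right[:, 1] = 0.5  # column 1 -> 2 crosses
        expected_right[:, 3] = 0.5  # wrap column 3 -> 0 crosses
        np.testing.assert_array_equal(g.w_right, expected_right)

    def test_weight_count_covers_torus(self):
        g = pattern_graph(np.zeros((5, 5)) + 1.0)
        assert g.w_right.size + g.w_down.size == 2 * 25


class TestResistanceMatrix:
    def test_triangle_closed_form(self):
        """Unit triangle: each pair sees 1 Ohm parallel to 2 Ohm -> 2/3."""
        A = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        R = resistance_matrix(A).R
        np.testing.assert_allclose(R[np.triu_indices(3, 1)], 2.0 / 3.0, atol=1e-12)
        np.testing.assert_allclose(np.diag(R), 0.0, atol=1e-14)

    def test_symmetry_and_pseudoinverse_oracle(self, rng):
        """(J + L)^(-1) construction equals the Laplacian-pseudoinverse form."""
        f = rng.uniform(0, 1, size=(4, 4))
        g = pattern_graph(f, eps_w=0.3)
        R = resistance_matrix(g).R
        L = g.laplacian().toarray()
        P = np.linalg.pinv(L)
        d = np.diag(P)
        R_oracle = d[:, None] + d[None, :] - 2 * P
        np.fill_diagonal(R_oracle, 0.0)
        np.testing.assert_allclose(R, R_oracle, atol=1e-9)
        np.testing.assert_allclose(R, R.T, atol=1e-12)

    def test_bounded_by_resistive_shortest_path(self, rng):
        """R(v, v') <= shortest path with edge lengths 1/weight."""
        for _ in range(20):
            A = random_connected_adjacency(rng)
            R = resistance_matrix(A).R
            G = nx.from_numpy_array(A)
            for u, v, data in G.edges(data=True):
                data["length"] = 1.0 / data["weight"]
            dists = dict(nx.all_pairs_dijkstra_path_length(G, weight="length"))
            for i in range(A.shape[0]):
                for j in range(A.shape[0]):
                    assert R[i, j] <= dists[i][j] + 1e-10

    def test_rayleigh_monotonicity(self, rng):
        """Lowering the interface conductance never lowers any resistance."""
        f = rng.uniform(0, 1, size=(5, 5))
        R_small = resistance_matrix(pattern_graph(f, eps_w=0.003)).R
        R_large = resistance_matrix(pattern_graph(f, eps_w=0.03)).R
        assert np.all(R_small >= R_large - 1e-10)

    def test_disconnected_graph_rejected(self):
        A = np.zeros((4, 4))
        A[0, 1] = A[1, 0] = 1.0
        A[2, 3] = A[3, 2] = 1.0
        with pytest.raises(ValueError):
            resistance_matrix(A)

    def test_grounded_solver_matches_dense_inverse(self, rng):
        """The fast column solver agrees with the dense (J+L)^(-1) route."""
        f = rng.uniform(0, 1, size=(6, 6))
        res = resistance_matrix(pattern_graph(f, eps_w=0.1))
        vals_dense = rdh(res, n_r=6, r=2.0, B=8, r_max=float(res.R.max()) + 1)
        vals_fast = collect_resistance_values(f, r=2.0, eps_w=0.1)
        fast_hist = rdh_from_values(vals_fast, B=8, r_max=float(res.R.max()) + 1)
        np.testing.assert_allclose(vals_dense.hist, fast_hist.hist, atol=1e-12)


class TestRDH:
    def test_histogram_is_in_simplex(self, rng):
        vals = rng.uniform(0, 5, size=1000)
        h = rdh_from_values(vals, B=12, r_max=5.0)
        assert h.hist.min() >= 0
        assert h.hist.sum() == pytest.approx(1.0)

    def test_single_bin_collects_everything(self, rng):
        vals = rng.uniform(0, 3, size=100)
        h = rdh_from_values(vals, B=1, r_max=3.0)
        np.testing.assert_array_equal(h.hist, [1.0])

    def test_overflow_values_dropped(self):
        h = rdh_from_values(np.array([0.5, 1.5, 9.0]), B=2, r_max=2.0)
        np.testing.assert_allclose(h.hist, [0.5, 0.5])

    def test_all_values_beyond_rmax_rejected(self):
        with pytest.raises(ValueError):
            rdh_from_values(np.array([5.0, 6.0]), B=4, r_max=1.0)

    def test_edge_transitive_torus_gives_indicator(self):
        """Unit-weight 6x6 torus, r=1: all neighbor resistances are equal,
        so the histogram is one-hot (brute-force enumeration oracle)."""
        res = resistance_matrix(pattern_graph(np.ones((6, 6))))
        r_max = 2.0 * res.R.max()
        feat = rdh(res, n_r=6, r=1.0, B=12, r_max=r_max)
        assert np.sort(feat.hist)[-1] == pytest.approx(1.0)
        # oracle: enumerate neighbor pairs explicitly
        vals = []
        for i in range(6):
            for j in range(6):
                v = i * 6 + j
                for di, dj in ((0, 1), (0, -1), (1, 0), (-1, 0)):
                    w = ((i + di) % 6) * 6 + (j + dj) % 6
                    vals.append(res.R[v, w])
        assert np.ptp(vals) < 1e-10

    def test_offsets_use_toroidal_distance(self):
        offs = {tuple(o) for o in torus_offsets(8, 1.0)}
        assert offs == {(0, 1), (0, 7), (1, 0), (7, 0)}

    def test_shift_invariance(self, pattern64):
        """Cyclic shifts of the pattern leave the RDH exactly unchanged."""
        f = pattern64.field[..., 0]
        a = pattern_rdh(f, r=8.0, r_max=20.0)
        b = pattern_rdh(np.roll(f, (11, -7), axis=(0, 1)), r=8.0, r_max=20.0)
        np.testing.assert_allclose(a.hist, b.hist, atol=1e-12)

    def test_rotation_and_transpose_invariance(self, pattern64):
        f = pattern64.field[..., 0]
        a = pattern_rdh(f, r=8.0, r_max=20.0)
        np.testing.assert_allclose(
            a.hist, pattern_rdh(np.rot90(f), r=8.0, r_max=20.0).hist, atol=1e-12
        )
        np.testing.assert_allclose(
            a.hist, pattern_rdh(f.T, r=8.0, r_max=20.0).hist, atol=1e-12
        )

    def test_range_reflection_symmetry(self, rng):
        """Reflecting the field about its mean preserves the weights/RDH."""
        f = rng.uniform(0, 1, size=(8, 8))
        mirrored = 2 * f.mean() - f
        a = pattern_rdh(f, r=2.0, r_max=50.0)
        b = pattern_rdh(mirrored, r=2.0, r_max=50.0)
        np.testing.assert_allclose(a.hist, b.hist, atol=1e-12)


class TestCalibration:
    def test_single_pattern_uses_own_quantile(self, rng):
        vals = rng.uniform(0, 1, size=500)
        assert calibrate_rmax([vals]) == pytest.approx(np.quantile(vals, 0.99))

    def test_maximum_over_patterns(self, rng):
        a = rng.uniform(0, 1, size=300)
        b = rng.uniform(0, 5, size=300)
        assert calibrate_rmax([a, b]) == pytest.approx(
            max(np.quantile(a, 0.99), np.quantile(b, 0.99))
        )

    def test_matches_sorted_order_statistics(self):
        sets = [np.arange(101.0), np.arange(50.0), 3.0 + np.arange(11.0)]
        expected = max(np.quantile(np.sort(s), 0.99) for s in sets)
        assert calibrate_rmax(sets) == pytest.approx(expected)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            calibrate_rmax([])


class TestScalarFeatures:
    def test_constant_field_maximal_concentration(self):
        assert max_concentration(np.full((8, 8), 5.0)) == pytest.approx(5.0)

    def test_bimodal_right_peak(self):
        f = np.concatenate([np.full(2048, 1.0), np.full(2048, 3.0)]).reshape(64, 64)
        bin_width = 2.0 / 25
        assert abs(max_concentration(f) - 3.0) <= bin_width

    def test_outlier_pixel_ignored(self):
        rng = np.random.default_rng(0)
        f = rng.uniform(0.9, 1.1, size=(64, 64))
        f[0, 0] = 100.0
        bin_width = (100.0 - f.min()) / 25
        assert abs(max_concentration(f) - 1.0) <= bin_width

    def test_constant_field_single_component(self):
        assert connected_components_feature(np.ones((8, 8))) == 1

    def test_disjoint_plateaus_counted(self):
        """Three separated high squares on a low background -> 3 components."""
        f = np.zeros((12, 12))
        f[1:3, 1:3] = 2.0
        f[6:8, 1:3] = 2.0
        f[1:3, 6:8] = 2.0
        assert connected_components_feature(f) == 3

    def test_wrapping_stripe_is_one_component(self):
        f = np.zeros((8, 8))
        f[3, :] = 5.0
        assert connected_components_feature(f) == 1
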
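"""Proportional thresholding, minimum connection density, windows and AUC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conncompare.density import (auc_over_window, find_crossover,
                                 minimum_connection_density,
                                 small_world_density_range,
                                 threshold_at_density)
from conncompare.io import (Connectome, DensityWindow, MetricCurve,
                            ValidationError, density_grid)
from conftest import symmetric_random_connectome


def conn_from_upper(vals, n):
    m = np.zeros((n, n))
    m[np.triu_indices(n, k=1)] = vals
    return Connectome(m + m.T)


class TestThreshold:
    def test_full_density_is_identity(self, random_connectome):
        thr = threshold_at_density(random_connectome, 1.0)
        assert np.array_equal(thr.matrix, random_connectome.matrix)

    def test_rank_selection_keeps_strongest(self):
        conn = conn_from_upper([0.9, 0.8, 0.5, 0.2, 0.1, 0.05], 4)
        thr = threshold_at_density(conn, 0.5)
        kept = sorted(thr.matrix[np.triu_indices(4, k=1)], reverse=True)[:3]
        assert kept == [0.9, 0.8, 0.5]
        assert np.count_nonzero(thr.matrix) == 6  # 3 edges, mirrored

    def test_tie_broken_lexicographically(self):
        # edges (0,1)=0.5, (0,2)=0.5, (1,2)=0.2; keep one -> (0,1) wins
        conn = conn_from_upper([0.5, 0.5, 0.2], 3)
        thr = threshold_at_density(conn, 1.0 / 3.0)
        assert thr.matrix[0, 1] == 0.5 and thr.matrix[0, 2] == 0.0

    def test_binarize_sets_unit_weights(self, random_connectome):
        thr = threshold_at_density(random_connectome, 0.4, binarize=True)
        assert set(np.unique(thr.matrix)) <= {0.0, 1.0}

    def test_density_below_one_edge_rejected(self, random_connectome):
        with pytest.raises(ValidationError):
            threshold_at_density(random_connectome, 1e-6)

    @given(d1=st.floats(0.1, 1.0), d2=st.floats(0.1, 1.0), seed=st.integers(0, 50))
    @settings(max_examples=40, deadline=None)
    def test_nestedness_property(self, d1, d2, seed):
        """Edges kept at a lower density are a subset of those at a higher."""
        rng = np.random.default_rng(seed)
        conn = symmetric_random_connectome(rng, n=12, density=0.7)
        lo, hi = sorted([d1, d2])
        m_lo = threshold_at_density(conn, lo).matrix != 0
        m_hi = threshold_at_density(conn, hi).matrix != 0
        assert not np.any(m_lo & ~m_hi)

    def test_achieved_density_close_to_target(self, random_connectome):
        thr = threshold_at_density(random_connectome, 0.3)
        n = random_connectome.n_nodes
        assert thr.density <= 0.3 + 1.0 / (n * (n - 1) / 2)


class TestMinimumConnectionDensity:
    def test_star_connects_once_all_spokes_present(self, rng):
        n = 32
        m = np.zeros((n, n))
        m[0, 1:] = rng.uniform(0.2, 1.0, n - 1)
        m += m.T
        conn = Connectome(m)
        grid = density_grid(0.01, 1.0, 0.01)
        d = minimum_connection_density([conn], grid)
        # needs all 31 spokes: first grid density keeping >= 31 of 496 edges
        assert d == pytest.approx(0.07)

    def test_disconnected_cliques_error(self):
        m = np.zeros((6, 6))
        for block in (range(3), range(3, 6)):
            for i in block:
                for j in block:
                    if i != j:
                        m[i, j] = 0.5
        with pytest.raises(ValidationError, match="disconnected"):
            minimum_connection_density([Connectome(m)],
                                       density_grid(0.1, 1.0, 0.1))

    def test_matches_exhaustive_scan(self, rng):
        import networkx as nx
        conns = [symmetric_random_connectome(rng, n=8, density=0.5)
                 for _ in range(4)]
        grid = density_grid(0.05, 1.0, 0.05)
        d = minimum_connection_density(conns, grid)
        # oracle: scan every grid density, check connectivity via networkx
        expected = None
        for cand in grid:
            ok = True
            for c in conns:
                g = nx.from_numpy_array(
                    threshold_at_density(c, float(cand)).matrix)
                ok &= nx.is_connected(g)
            if ok:
                expected = float(cand)
                break
        assert d == expected

    def test_monotone_under_weakest_edge_addition(self, rng):
        """Appending a weakest-ranked edge never raises the minimum density.

        (A strong added edge can displace kept edges at a fixed rank cutoff,
        so monotonicity is stated for additions at the bottom of the
        ranking.)
        """
        conns = [symmetric_random_connectome(rng, n=10, density=0.4)
                 for _ in range(3)]
        grid = density_grid(0.02, 1.0, 0.02)
        d_before = minimum_connection_density(conns, grid)
        boosted = []
        for c in conns:
            m = c.matrix.copy()
            absent = np.argwhere((m == 0) & ~np.eye(10, dtype=bool))
            i, j = absent[0]
            weakest = m[m > 0].min()
            m[i, j] = m[j, i] = weakest / 2.0
            boosted.append(Connectome(m))
        assert minimum_connection_density(boosted, grid) <= d_before


class TestSmallWorldRange:
    def grid(self):
        return density_grid(0.24, 0.6, 0.01)

    def test_capped_at_half_density(self):
        curves = [MetricCurve("sigma", self.grid(),
                              np.full(self.grid().size, 1.5), "s1")]
        win = small_world_density_range(curves, 0.24)
        assert win.d_lo == 0.24 and win.d_hi == pytest.approx(0.5)

    def test_ends_before_sigma_drops_to_one(self):
        grid = self.grid()
        vals = np.where(grid < 0.4 - 1e-9, 1.5, 0.9)
        win = small_world_density_range(
            [MetricCurve("sigma", grid, vals, "s1")], 0.24)
        assert win.d_hi == pytest.approx(0.39)

    def test_no_small_world_regime_is_error(self):
        curves = [MetricCurve("sigma", self.grid(),
                              np.full(self.grid().size, 0.8), "s1")]
        with pytest.raises(ValidationError, match="small-world"):
            small_world_density_range(curves, 0.24)

    def test_all_rule_stricter_than_mean_rule(self):
        grid = self.grid()
        hi = np.full(grid.size, 2.0)
        lo = np.where(grid < 0.35, 1.2, 0.7)
        curves = [MetricCurve("sigma", grid, hi, "a"),
                  MetricCurve("sigma", grid, lo, "b")]
        win_mean = small_world_density_range(curves, 0.24, rule="mean")
        win_all = small_world_density_range(curves, 0.24, rule="all")
        assert win_all.d_hi <= win_mean.d_hi


class TestCrossover:
    def test_first_sign_change_density(self):
        grid = np.array([0.24, 0.30, 0.34, 0.40])
        a = MetricCurve("sigma", grid, np.array([2.0, 2.0, 1.0, 1.0]))
        b = MetricCurve("sigma", grid, np.array([1.5, 1.5, 1.5, 1.5]))
        assert find_crossover(a, b) == pytest.approx(0.34)

    def test_identical_curves_no_crossover(self):
        grid = np.array([0.2, 0.3, 0.4])
        a = MetricCurve("m", grid, np.array([1.0, 2.0, 3.0]))
        b = MetricCurve("m", grid, np.array([1.0, 2.0, 3.0]))
        assert find_crossover(a, b) is None

    def test_dominating_curve_no_crossover(self):
        grid = np.array([0.2, 0.3, 0.4])
        a = MetricCurve("m", grid, np.array([2.0, 2.1, 2.2]))
        b = MetricCurve("m", grid, np.array([1.0, 1.1, 1.2]))
        assert find_crossover(a, b) is None


class TestAuc:
    def test_constant_curve_rectangle(self):
        grid = density_grid(0.2, 0.6, 0.01)
        curve = MetricCurve("m", grid, np.full(grid.size, 2.0))
        assert auc_over_window(curve, DensityWindow(0.3, 0.5)) == \
            pytest.approx(0.4)

    def test_linear_curve_triangle(self):
        grid = density_grid(0.01, 1.0, 0.01)
        curve = MetricCurve("m", grid, grid.copy())
        auc = auc_over_window(curve, DensityWindow(0.01, 1.0))
        assert auc == pytest.approx((1.0**2 - 0.01**2) / 2, abs=1e-12)

    def test_matches_manual_trapezoid_sum(self, rng):
        grid = density_grid(0.1, 0.9, 0.02)
        vals = rng.uniform(0, 3, size=grid.size)
        curve = MetricCurve("m", grid, vals)
        manual = sum((vals[i] + vals[i + 1]) / 2 * (grid[i + 1] - grid[i])
                     for i in range(grid.size - 1))
        assert auc_over_window(curve, DensityWindow(0.1, 0.9)) == \
            pytest.approx(manual, abs=1e-12)

    @given(seed=st.integers(0, 100))
    @settings(max_examples=30, deadline=None)
    def test_additivity_property(self, seed):
        rng = np.random.default_rng(seed)
        grid = density_grid(0.1, 0.7, 0.05)
        curve = MetricCurve("m", grid, rng.uniform(0, 5, grid.size))
        whole = auc_over_window(curve, DensityWindow(0.1, 0.7))
        parts = auc_over_window(curve, DensityWindow(0.1, 0.4)) + \
            auc_over_window(curve, DensityWindow(0.4, 0.7))
        assert whole == pytest.approx(parts, abs=1e-12)

    def test_window_off_grid_rejected(self):
        grid = density_grid(0.2, 0.6, 0.05)
        curve = MetricCurve("m", grid, np.ones(grid.size))
        with pytest.raises(ValidationError, match="grid"):
            auc_over_window(curve, DensityWindow(0.21, 0.5))
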
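import numpy as np
import pytest

from pollinet import connectivity as cn
from pollinet import pinchpoints as pp
from pollinet.grid import RasterGrid

from conftest import random_resistance_grid


def brute_force_cost(surface, src_rc, tgt_rc):
    """Exhaustive minimum over all simple paths (branch-and-bound DFS:
    prunes only partial paths already costlier than the best complete
    one, so the returned optimum equals full enumeration)."""
    r = surface.grid.data
    n_rows, n_cols = r.shape
    cell = surface.grid.cell_size
    best = [np.inf]

    def nbrs(i, j):
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if (di, dj) == (0, 0):
                    continue
                ii, jj = i + di, j + dj
                if 0 <= ii < n_rows and 0 <= jj < n_cols and np.isfinite(r[ii, jj]):
                    d = np.sqrt(2) if di and dj else 1.0
                    yield ii, jj, d * (r[i, j] + r[ii, jj]) / 2 * cell

    def dfs(i, j, cost, seen):
        if cost >= best[0]:
            return
        if (i, j) == tgt_rc:
            best[0] = cost
            return
        for ii, jj, w in nbrs(i, j):
            if (ii, jj) not in seen:
                dfs(ii, jj, cost + w, seen | {(ii, jj)})

    dfs(*src_rc, 0.0, {src_rc})
    return best[0]


class TestCostDistance:
    def test_uniform_strip(self):
        s = cn.ResistanceSurface(RasterGrid(np.ones((1, 4)), 1.0), 1e-3)
        f = pp.cost_distance(s, (np.array([0]), np.array([0])))
        assert np.allclose(f.grid.data, [[0.0, 1.0, 2.0, 3.0]])

    def test_series_strip(self):
        s = cn.ResistanceSurface(RasterGrid(np.array([[1.0, 2.0, 3.0]]), 1.0), 1e-3)
        f = pp.cost_distance(s, (np.array([0]), np.array([0])))
        assert np.allclose(f.grid.data, [[0.0, 1.5, 4.0]])

    def test_matches_exhaustive_path_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            s = random_resistance_grid(rng, (4, 4))
            f = pp.cost_distance(s, (np.array([0]), np.array([0])))
            for tgt in [(3, 3), (1, 2), (3, 0)]:
                assert f.grid.data[tgt] == pytest.approx(
                    brute_force_cost(s, (0, 0), tgt), abs=1e-9
                )

    def test_unreachable_cells_infinite(self):
        r = np.ones((1, 4))
        r[0, 2] = np.nan
        s = cn.ResistanceSurface(RasterGrid(r, 1.0), 1e-3)
        f = pp.cost_distance(s, (np.array([0]), np.array([0])))
        assert np.isinf(f.grid.data[0, 3])

    def test_empty_source_rejected(self):
        s = cn.ResistanceSurface(RasterGrid(np.ones((2, 2)), 1.0), 1e-3)
        with pytest.raises(ValueError):
            pp.cost_distance(s, (np.array([]), np.array([])))


class TestCorridor:
    def _fields(self, shape=(5, 9)):
        s = cn.ResistanceSurface(RasterGrid(np.ones(shape), 1.0), 1e-3)
        a = pp.cost_distance(s, (np.array([2]), np.array([0])))
        b = pp.cost_distance(s, (np.array([2]), np.array([shape[1] - 1])))
        return s, a, b

    def test_zero_cutoff_is_lcp_cells(self):
        s, a, b = self._fields()
        mask, lcp = pp.least_cost_corridor(a, b, 0.0)
        # on a uniform strip the LCP runs along the middle row
        assert lcp == pytest.approx(8.0)
        assert mask[2, :].all()
        total = a.grid.data + b.grid.data
        assert set(map(tuple, np.argwhere(mask))) == set(
            map(tuple, np.argwhere(np.isclose(total, lcp)))
        )

    def test_infinite_cutoff_includes_all_reachable(self):
        s, a, b = self._fields()
        mask, _ = pp.least_cost_corridor(a, b, np.inf)
        assert mask.all()

    def test_cutoff_band_matches_direct_evaluation(self):
        s, a, b = self._fields()
        cutoff = 2.0
        mask, lcp = pp.least_cost_corridor(a, b, cutoff)
        total = a.grid.data + b.grid.data
        oracle = np.isfinite(total) & (total <= lcp + cutoff + 1e-12)
        assert np.array_equal(mask, oracle)

    def test_monotone_in_cutoff_and_symmetric(self):
        s, a, b = self._fields()
        m1, l1 = pp.least_cost_corridor(a, b, 1.0)
        m2, l2 = pp.least_cost_corridor(a, b, 3.0)
        assert np.all(m2[m1])  # nested masks
        mba, lba = pp.least_cost_corridor(b, a, 1.0)
        assert l1 == pytest.approx(lba, abs=1e-10)


class TestCorridorCurrent:
    def test_full_grid_corridor_equals_unrestricted_solve(self):
        rng = np.random.default_rng(1)
        s = random_resistance_grid(rng, (6, 6))
        mask = np.ones((6, 6), bool)
        src = (np.array([0]), np.array([0]))
        tgt = (np.array([5]), np.array([5]))
        cur, sol = pp.corridor_current(s, mask, src, tgt)
        g = cn.build_lattice_graph(s)
        ref = cn.solve_pair(g, g.node_index[src], g.node_index[tgt])
        direct = np.full((6, 6), np.nan)
        direct[tuple(g.cells.T)] = ref.cell_current
        ok = np.isfinite(direct)
        assert np.allclose(cur.data[ok], direct[ok], atol=1e-10)
        assert sol.effective_resistance == pytest.approx(ref.effective_resistance, abs=1e-10)

    def test_one_cell_wide_corridor_series_current(self):
        s = cn.ResistanceSurface(RasterGrid(np.ones((3, 7)), 1.0), 1e-3)
        mask = np.zeros((3, 7), bool)
        mask[1, :] = True
        cur, sol = pp.corridor_current(
            s, mask, (np.array([1]), np.array([0])), (np.array([1]), np.array([6]))
        )
        assert np.allclose(cur.data[1, 1:6], 1.0, atol=1e-10)

    def test_hourglass_waist_carries_peak_current(self):
        mask = np.ones((5, 11), bool)
        mask[[0, 1, 3, 4], 5] = False  # one-cell waist in the middle column
        s = cn.ResistanceSurface(RasterGrid(np.ones((5, 11)), 1.0), 1e-3)
        cur, sol = pp.corridor_current(
            s, mask, (np.full(5, np.arange(5)), np.zeros(5, int)),
            (np.full(5, np.arange(5)), np.full(5, 10)),
        )
        waist = cur.data[2, 5]
        others = np.nansum(cur.data) - waist
        assert waist == np.nanmax(cur.data)
        assert waist == pytest.approx(1.0, abs=1e-9)  # all current through the waist

    def test_disconnected_corridor_unreachable(self):
        mask = np.ones((1, 5), bool)
        mask[0, 2] = False
        s = cn.ResistanceSurface(RasterGrid(np.ones((1, 5)), 1.0), 1e-3)
        cur, sol = pp.corridor_current(
            s, mask, (np.array([0]), np.array([0])), (np.array([0]), np.array([4]))
        )
        assert not sol.reachable
        assert np.isinf(sol.effective_resistance)


class TestPinchPointExtraction:
    def brute_force_clusters(self, data, thr):
        """Independent flood-fill over thresholded cells."""
        mask = np.isfinite(data) & (data >= thr)
        seen = np.zeros_like(mask, bool)
        clusters = []
        for i, j in np.argwhere(mask):
            if seen[i, j]:
                continue
            stack, members = [(i, j)], []
            seen[i, j] = True
            while stack:
                a, b = stack.pop()
                members.append((a, b))
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        ii, jj = a + di, b + dj
                        if (
                            0 <= ii < mask.shape[0]
                            and 0 <= jj < mask.shape[1]
                            and mask[ii, jj]
                            and not seen[ii, jj]
                        ):
                            seen[ii, jj] = True
                            stack.append((ii, jj))
            clusters.append(frozenset(members))
        return {c for c in clusters if len(c) >= 2}

    def test_constructed_pair_above_background(self):
        rng = np.random.default_rng(2)
        data = rng.uniform(0, 0.5, (15, 15))
        data[7, 7] = data[7, 8] = 10.0
        clusters = pp.extract_pinch_points(RasterGrid(data, 100.0), percentile=99)
        assert len(clusters) == 1
        assert clusters[0].area_m2 == pytest.approx(2 * 100.0**2)
        assert clusters[0].max_current == 10.0

    def test_isolated_singletons_yield_no_cluster(self):
        rng = np.random.default_rng(3)
        data = rng.uniform(0, 0.5, (15, 15))
        data[2, 2] = data[12, 12] = data[7, 3] = 10.0  # mutually non-adjacent
        clusters = pp.extract_pinch_points(RasterGrid(data, 100.0), percentile=99)
        assert clusters == []

    def test_matches_flood_fill_oracle(self):
        rng = np.random.default_rng(4)
        data = rng.uniform(0, 1, (20, 20))
        g = RasterGrid(data, 100.0)
        clusters = pp.extract_pinch_points(g, percentile=90)
        thr = np.percentile(data, 90)
        oracle = self.brute_force_clusters(data, thr)
        got = {frozenset(map(tuple, c.cells.tolist())) for c in clusters}
        assert got == oracle

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        data = rng.uniform(0, 1, (20, 20))
        c1 = pp.extract_pinch_points(RasterGrid(data, 100.0), percentile=95)
        c2 = pp.extract_pinch_points(RasterGrid(np.exp(4 * data), 100.0), percentile=95)
        s1 = {frozenset(map(tuple, c.cells.tolist())) for c in c1}
        s2 = {frozenset(map(tuple, c.cells.tolist())) for c in c2}
        assert s1 == s2

    def test_small_sample_warns_and_constant_yields_none(self):
        with pytest.warns(UserWarning):
            pp.extract_pinch_points(RasterGrid(np.random.default_rng(6).uniform(0, 1, (5, 5)), 1.0))
        with pytest.warns(UserWarning):
            out = pp.extract_pinch_points(RasterGrid(np.full((20, 20), 2.0), 1.0))
        assert out == []


class TestPinchPointAnalysis:
    def test_two_critical_cores_yield_waist_cluster(self):
        # suitable ends, one narrow high-suitability bridge: pinch on bridge
        data = np.full((9, 15), 0.3)
        data[3:6, 0:2] = 0.95
        data[3:6, 13:15] = 0.95
        data[4, 2:13] = 0.6  # corridor row
        combined = RasterGrid(data, 100.0)
        surface = cn.suitability_to_resistance(combined)
        clusters, cores, cur = pp.pinch_point_analysis(
            surface, combined, tau_critical=0.9, link_dist_m=1e9,
            percentile=85.0,  # small fixture: top 1% of ~10^2 cells is a singleton
        )
        assert cores.n_groups == 2
        assert len(clusters) >= 1
        rows = {r for c in clusters for r, _ in map(tuple, c.cells.tolist())}
        assert 4 in rows  # clusters sit on the bridge row

    def test_fewer_than_two_cores_warns(self):
        combined = RasterGrid(np.full((6, 6), 0.3), 100.0)
        surface = cn.suitability_to_resistance(combined)
        with pytest.warns(UserWarning):
            clusters, cores, cur = pp.pinch_point_analysis(surface, combined)
        assert clusters == []
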
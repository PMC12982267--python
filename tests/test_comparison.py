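import numpy as np
import pandas as pd
import pytest
import shapely

from pollinet import comparison as cp
from pollinet.grid import RasterGrid
from pollinet.pinchpoints import PinchPointCluster


class TestTopFractionMask:
    def test_distinct_values_exact_count(self):
        rng = np.random.default_rng(0)
        vals = rng.permutation(100).astype(float)
        g = RasterGrid(vals.reshape(10, 10), 100.0)
        mask = cp.top_fraction_mask(g, 0.10)
        assert mask.sum() == 10
        assert set(vals[mask.ravel()]) == set(range(90, 100))

    def test_constant_map_all_included(self):
        g = RasterGrid(np.full((5, 5), 3.0), 100.0)
        assert cp.top_fraction_mask(g, 0.10).all()

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(1)
        g = RasterGrid(rng.uniform(0, 1, (20, 20)), 100.0)
        mask = cp.top_fraction_mask(g, 0.10)
        flat = np.sort(g.data.ravel())
        thr = flat[int(np.ceil(0.9 * (len(flat) - 1)))]
        oracle = g.data >= np.quantile(g.data, 0.9)
        assert np.array_equal(mask, oracle)

    def test_all_nodata_rejected(self):
        with pytest.raises(ValueError):
            cp.top_fraction_mask(RasterGrid(np.full((3, 3), np.nan), 1.0), 0.1)


class TestGapAnalysis:
    def _grid(self):
        return RasterGrid(np.zeros((10, 10)), 1.0)

    def test_constructed_quadrants(self):
        grid = self._grid()
        mask = np.zeros((10, 10), bool)
        mask[0:5, :] = True  # top half (rows 0-4)
        # polygons: left five columns, full height
        poly = shapely.box(0.0, 0.0, 5.0, 10.0)
        part = cp.gap_analysis(mask, [poly], grid)
        counts = part.counts()
        assert counts == {"both": 25, "species_only": 25, "planner_only": 25, "neither": 25}
        areas = part.area_km2()
        assert sum(areas.values()) == pytest.approx(100 * 1.0 / 1e6)

    def test_identical_masks_no_exclusive_areas(self):
        grid = self._grid()
        mask = np.zeros((10, 10), bool)
        mask[3:7, 3:7] = True
        poly = shapely.box(3.0, 3.0, 7.0, 7.0)
        part = cp.gap_analysis(mask, [poly], grid)
        counts = part.counts()
        assert counts["species_only"] == 0
        assert counts["planner_only"] == 0
        assert counts["both"] == 16

    def test_random_case_matches_cellwise_oracle(self):
        rng = np.random.default_rng(2)
        grid = self._grid()
        mask = rng.uniform(0, 1, (10, 10)) < 0.4
        polys = [shapely.box(*sorted(rng.uniform(0, 10, 2)), *sorted(rng.uniform(0, 10, 2)))
                 for _ in range(3)]
        part = cp.gap_analysis(mask, polys, grid)
        union = shapely.unary_union(polys)
        X, Y = grid.cell_centers()
        for i in range(10):
            for j in range(10):
                planner = union.contains(shapely.Point(X[i, j], Y[i, j]))
                expect = (
                    "both" if mask[i, j] and planner
                    else "species_only" if mask[i, j]
                    else "planner_only" if planner
                    else "neither"
                )
                assert part.labels[i, j] == expect

    def test_empty_planner_layer_noted(self):
        grid = self._grid()
        mask = np.zeros((10, 10), bool)
        mask[0, 0] = True
        with pytest.warns(UserWarning):
            part = cp.gap_analysis(mask, [], grid)
        counts = part.counts()
        assert counts["planner_only"] == counts["both"] == 0

    def test_partition_is_exhaustive(self):
        rng = np.random.default_rng(3)
        data = np.zeros((8, 8))
        data[0, 0] = np.nan  # one nodata cell
        grid = RasterGrid(data, 1.0)
        mask = rng.uniform(0, 1, (8, 8)) < 0.5
        part = cp.gap_analysis(mask, [shapely.box(2, 2, 6, 6)], grid)
        assert sum(part.counts().values()) == 63  # all valid cells labelled


class TestRelativeProbability:
    def _partition(self):
        grid = RasterGrid(np.zeros((10, 10)), 1.0)
        mask = np.zeros((10, 10), bool)
        mask[0:5, :] = True
        poly = shapely.box(0.0, 0.0, 5.0, 10.0)
        return cp.gap_analysis(mask, [poly], grid)

    def test_definitional_arithmetic(self):
        part = self._partition()
        # presences 60% in "both" cells (rows 0-4 x cols 0-4), 40% neither
        pres = pd.DataFrame({
            "x": [1.5] * 6 + [8.5] * 4,
            "y": [8.5] * 6 + [1.5] * 4,
        })
        rep = cp.relative_probability(part, pres, n_background=40000, seed=0)
        both = rep.set_index("category").loc["both"]
        # background fraction for "both" is ~25% -> ratio ~ 0.6/0.25
        assert both["ratio"] == pytest.approx(0.6 / both["background_fraction"], rel=1e-12)
        assert both["ratio"] == pytest.approx(2.4, rel=0.05)

    def test_uniform_presences_give_unit_ratios(self):
        part = self._partition()
        rng = np.random.default_rng(4)
        pres = pd.DataFrame({"x": rng.uniform(0, 10, 5000), "y": rng.uniform(0, 10, 5000)})
        rep = cp.relative_probability(part, pres, n_background=20000, seed=5)
        assert np.all(np.abs(rep["ratio"].to_numpy() - 1.0) < 0.1)

    def test_empty_category_zero_ratio(self):
        part = self._partition()
        pres = pd.DataFrame({"x": [1.0, 2.0], "y": [8.0, 9.0]})  # all in "both"
        rep = cp.relative_probability(part, pres, n_background=10000, seed=6)
        neither = rep.set_index("category").loc["neither"]
        assert neither["ratio"] == 0.0

    def test_outside_presences_dropped_and_counted(self):
        part = self._partition()
        pres = pd.DataFrame({"x": [1.0, 100.0], "y": [8.0, 100.0]})
        rep = cp.relative_probability(part, pres, n_background=1000, seed=7)
        assert rep.attrs["n_dropped_outside"] == 1
        assert rep.attrs["n_presences"] == 1

    def test_fractions_sum_to_one(self):
        part = self._partition()
        rng = np.random.default_rng(8)
        pres = pd.DataFrame({"x": rng.uniform(0, 10, 200), "y": rng.uniform(0, 10, 200)})
        rep = cp.relative_probability(part, pres, n_background=5000, seed=9)
        assert rep["presence_fraction"].sum() == pytest.approx(1.0)
        assert rep["background_fraction"].sum() == pytest.approx(1.0)


class TestDescriptives:
    def test_ring_mean_distance_equals_radius(self):
        grid = RasterGrid(np.zeros((21, 21)), 1.0)
        X, Y = grid.cell_centers()
        centre = (X[10, 10], Y[10, 10])
        d = np.hypot(X - centre[0], Y - centre[1])
        ring = np.isclose(d, 5.0, atol=0.2)
        labels = np.full((21, 21), "neither", dtype=object)
        labels[ring] = "both"
        part = cp.CategoryPartition(labels, grid)
        fine = RasterGrid(np.zeros((21, 21)), 1.0)
        out = cp.corridor_descriptives(part, fine, centre, {"zero": 0.0})
        both = out.set_index("category").loc["both"]
        assert both["mean_dist_m"] == pytest.approx(5.0, abs=0.2)

    def test_single_class_category_proportion_one(self):
        grid = RasterGrid(np.zeros((4, 4)), 10.0)
        labels = np.full((4, 4), "species_only", dtype=object)
        part = cp.CategoryPartition(labels, grid)
        fine = RasterGrid(np.full((8, 8), 3.0), 5.0)
        out = cp.corridor_descriptives(part, fine, (20.0, 20.0), {"grass": 3.0, "wood": 0.0})
        row = out.set_index("category").loc["species_only"]
        assert row["prop_grass"] == 1.0
        assert row["prop_wood"] == 0.0

    def test_random_partition_matches_tabulation_oracle(self):
        rng = np.random.default_rng(10)
        grid = RasterGrid(np.zeros((6, 6)), 10.0)
        cats = np.array(cp.CATEGORIES)
        labels = cats[rng.integers(0, 4, (6, 6))].astype(object)
        part = cp.CategoryPartition(labels, grid)
        fine = RasterGrid(rng.integers(0, 3, (12, 12)).astype(float), 5.0)
        out = cp.corridor_descriptives(part, fine, (30.0, 30.0), {"c1": 1.0})
        fx, fy = fine.cell_centers()
        cat_fine = part.category_at(fx.ravel(), fy.ravel())
        for c in cp.CATEGORIES:
            sel = cat_fine == c
            if not sel.any():
                continue
            expect = float(np.mean(fine.data.ravel()[sel] == 1.0))
            got = out.set_index("category").loc[c, "prop_c1"]
            assert got == pytest.approx(expect, abs=1e-12)

    def test_empty_category_flagged_nan(self):
        grid = RasterGrid(np.zeros((3, 3)), 1.0)
        labels = np.full((3, 3), "neither", dtype=object)
        part = cp.CategoryPartition(labels, grid)
        fine = RasterGrid(np.zeros((3, 3)), 1.0)
        out = cp.corridor_descriptives(part, fine, (1.5, 1.5), {"z": 0.0})
        assert np.isnan(out.set_index("category").loc["both", "mean_dist_m"])


class TestPinchOverlap:
    def _cluster(self, cells):
        cells = np.asarray(cells)
        return PinchPointCluster(cells=cells, area_m2=len(cells) * 1.0,
                                 max_current=1.0, mean_current=1.0)

    def test_cluster_inside_polygon(self):
        grid = RasterGrid(np.zeros((10, 10)), 1.0)
        poly = shapely.box(0.0, 0.0, 10.0, 10.0)
        out = cp.pinch_overlap([self._cluster([(2, 2), (2, 3)])], [poly], grid)
        assert out == {"n_in": 1, "n_out": 0, "area_in_km2": 2 / 1e6, "area_out_km2": 0.0}

    def test_straddling_cluster_counts_inside_whole(self):
        grid = RasterGrid(np.zeros((10, 10)), 1.0)
        poly = shapely.box(0.0, 0.0, 3.0, 10.0)  # covers cols 0-2 centres
        cluster = self._cluster([(5, 2), (5, 3), (5, 4)])  # one cell in, two out
        out = cp.pinch_overlap([cluster], [poly], grid)
        assert out["n_in"] == 1
        assert out["area_in_km2"] == pytest.approx(3 / 1e6)  # whole area attributed

    def test_random_clusters_match_point_in_polygon_oracle(self):
        rng = np.random.default_rng(11)
        grid = RasterGrid(np.zeros((20, 20)), 1.0)
        polys = [shapely.box(2, 2, 9, 9), shapely.box(12, 12, 18, 18)]
        union = shapely.unary_union(polys)
        X, Y = grid.cell_centers()
        clusters = []
        for _ in range(10):
            i, j = rng.integers(0, 19, 2)
            clusters.append(self._cluster([(i, j), (i, j + 1)]))
        out = cp.pinch_overlap(clusters, polys, grid)
        n_in = 0
        for c in clusters:
            pts = [shapely.Point(X[r, cc], Y[r, cc]) for r, cc in c.cells]
            n_in += any(union.contains(p) for p in pts)
        assert out["n_in"] == n_in
        assert out["n_in"] + out["n_out"] == 10

    def test_empty_cluster_list_zeros(self):
        grid = RasterGrid(np.zeros((2, 2)), 1.0)
        out = cp.pinch_overlap([], [shapely.box(0, 0, 1, 1)], grid)
        assert out["n_in"] == out["n_out"] == 0
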
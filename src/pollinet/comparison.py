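"""Gap analysis between the species-based corridor mask and an
independently supplied planner corridor network.

The species-based corridors are the top 10% of cumulative-current values;
planner polygons are rasterised by cell-centre coverage onto the same
grid. Every valid cell then carries one of four labels — covered by both
networks, by the species-based one only, by the planner one only, or by
neither — and the partition is validated against independent presence
records via relative probabilities (presence fraction over background
fraction per category).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely

from .grid import RasterGrid
from .pinchpoints import PinchPointCluster

__all__ = [
    "CategoryPartition",
    "top_fraction_mask",
    "rasterise_polygons",
    "gap_analysis",
    "relative_probability",
    "corridor_descriptives",
    "pinch_overlap",
]

CATEGORIES = ("both", "species_only", "planner_only", "neither")


def top_fraction_mask(current: RasterGrid, fraction: float = 0.10) -> np.ndarray:
    """Cells at or above the (1-fraction) quantile of finite current
    values; ties at the threshold are included (so a constant map is all
    True — the documented degenerate case)."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0,1)")
    vals = current.data[np.isfinite(current.data)]
    if vals.size == 0:
        raise ValueError("current map has no finite cells")
    thr = float(np.quantile(vals, 1.0 - fraction))
    return np.isfinite(current.data) & (current.data >= thr)


def rasterise_polygons(polygons, grid: RasterGrid) -> np.ndarray:
    """Boolean mask of cells whose centre is covered by any polygon."""
    if not polygons:
        return np.zeros(grid.shape, bool)
    union = shapely.unary_union(list(polygons))
    X, Y = grid.cell_centers()
    return shapely.contains_xy(union, X.ravel(), Y.ravel()).reshape(grid.shape)


@dataclass
class CategoryPartition:
    labels: np.ndarray  # string codes per cell, '' on nodata
    grid: RasterGrid

    def area_km2(self) -> dict[str, float]:
        cell = self.grid.cell_size**2 / 1e6
        return {c: float(np.sum(self.labels == c) * cell) for c in CATEGORIES}

    def counts(self) -> dict[str, int]:
        return {c: int(np.sum(self.labels == c)) for c in CATEGORIES}

    def category_at(self, x, y) -> np.ndarray:
        row, col = self.grid.index_of(x, y)
        out = np.full(np.shape(row), "", dtype=object)
        inside = row >= 0
        out[inside] = self.labels[row[inside], col[inside]]
        return out


def gap_analysis(species_mask: np.ndarray, planner_polygons, grid: RasterGrid) -> CategoryPartition:
    """Four-way overlay of the species-based mask and the planner
    polygons over valid cells."""
    if not planner_polygons:
        warnings.warn("empty planner layer: planner categories will be empty")
    planner = rasterise_polygons(planner_polygons, grid)
    labels = np.full(grid.shape, "", dtype=object)
    valid = grid.valid
    labels[valid & species_mask & planner] = "both"
    labels[valid & species_mask & ~planner] = "species_only"
    labels[valid & ~species_mask & planner] = "planner_only"
    labels[valid & ~species_mask & ~planner] = "neither"
    return CategoryPartition(labels, grid)


def relative_probability(
    partition: CategoryPartition,
    presences: pd.DataFrame,
    n_background: int = 20000,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Relative probability of presence per category.

    Independent presences and ``n_background`` uniform random points over
    valid cells are assigned to categories by their containing cell; the
    ratio of presence fraction to background fraction per category is the
    relative probability (ratio > 1: presences over-represented there).
    Presences outside the grid are dropped and counted.
    """
    if len(presences) == 0:
        raise ValueError("need at least one presence")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cat_p = partition.category_at(presences["x"].to_numpy(float), presences["y"].to_numpy(float))
    dropped = int(np.sum(cat_p == ""))
    cat_p = cat_p[cat_p != ""]

    valid = partition.grid.valid & (partition.labels != "")
    rr, cc = np.nonzero(valid)
    idx = rng.integers(0, rr.size, n_background)
    # uniform over valid cells with within-cell jitter
    cat_b = partition.labels[rr[idx], cc[idx]]

    rows = []
    n_p, n_b = len(cat_p), n_background
    for c in CATEGORIES:
        fp = float(np.sum(cat_p == c)) / n_p if n_p else np.nan
        fb = float(np.sum(cat_b == c)) / n_b
        ratio = fp / fb if fb > 0 else (np.nan if fp > 0 else 0.0)
        rows.append({"category": c, "presence_fraction": fp, "background_fraction": fb,
                     "ratio": ratio, "undefined": fb == 0 and fp > 0})
    out = pd.DataFrame(rows)
    out.attrs["n_presences"] = n_p
    out.attrs["n_background"] = n_b
    out.attrs["n_dropped_outside"] = dropped
    return out


def corridor_descriptives(
    partition: CategoryPartition,
    landcover_fine: RasterGrid,
    centre_xy: tuple[float, float],
    class_codes: dict[str, float],
) -> pd.DataFrame:
    """Per category: mean/median distance of member cell centres to the
    city centre, and fine land-cover class proportions within the member
    cells (fine cells whose centre falls in a member analysis cell)."""
    X, Y = partition.grid.cell_centers()
    fx, fy = landcover_fine.cell_centers()
    cat_fine = partition.category_at(fx.ravel(), fy.ravel())
    rows = []
    for c in CATEGORIES:
        sel = partition.labels == c
        if not sel.any():
            rows.append({"category": c, "n_cells": 0, "mean_dist_m": np.nan,
                         "median_dist_m": np.nan,
                         **{f"prop_{k}": np.nan for k in class_codes}})
            continue
        d = np.hypot(X[sel] - centre_xy[0], Y[sel] - centre_xy[1])
        fine_sel = cat_fine == c
        fine_vals = landcover_fine.data.ravel()[fine_sel]
        fine_vals = fine_vals[np.isfinite(fine_vals)]
        props = {
            f"prop_{k}": float(np.mean(fine_vals == code)) if fine_vals.size else np.nan
            for k, code in class_codes.items()
        }
        rows.append({"category": c, "n_cells": int(sel.sum()),
                     "mean_dist_m": float(d.mean()), "median_dist_m": float(np.median(d)),
                     **props})
    return pd.DataFrame(rows)


def pinch_overlap(clusters: list[PinchPointCluster], planner_polygons, grid: RasterGrid) -> dict:
    """Count pinch-point clusters inside/outside the planner network.

    A cluster counts as overlapping when any member cell centre falls in a
    planner polygon; its whole area is then attributed inside (clusters
    are counted, not split).
    """
    if not clusters:
        return {"n_in": 0, "n_out": 0, "area_in_km2": 0.0, "area_out_km2": 0.0}
    union = shapely.unary_union(list(planner_polygons)) if planner_polygons else None
    X, Y = grid.cell_centers()
    n_in = n_out = 0
    area_in = area_out = 0.0
    for cl in clusters:
        rr, cc = cl.cells[:, 0], cl.cells[:, 1]
        inside = (
            bool(shapely.contains_xy(union, X[rr, cc], Y[rr, cc]).any())
            if union is not None
            else False
        )
        if inside:
            n_in += 1
            area_in += cl.area_m2
        else:
            n_out += 1
            area_out += cl.area_m2
    return {
        "n_in": n_in,
        "n_out": n_out,
        "area_in_km2": area_in / 1e6,
        "area_out_km2": area_out / 1e6,
    }
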
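"""Least-cost corridors between critical core areas and pinch-point
extraction.

Critical core areas (suitability > 0.9) are the most confidently suitable
habitat; the corridor between a pair of them is the band of cells whose
summed cost-weighted distances to the two cores stay within a cutoff of
the least-cost-path cost. Solving the circuit restricted to a corridor
concentrates current where the corridor narrows; cells in the top 1% of
current values, grouped by queen adjacency into clusters of two or more
cells, are the pinch points — places where losing a few cells would
disproportionately cut connectivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra as _sparse_dijkstra

from .grid import RasterGrid
from .connectivity import (
    QUEEN,
    CoreAreaSet,
    ResistanceSurface,
    build_lattice_graph,
    solve_pair,
    delineate_core_areas,
    PairSolve,
)

__all__ = [
    "CostDistanceField",
    "PinchPointCluster",
    "cost_distance",
    "least_cost_corridor",
    "corridor_current",
    "extract_pinch_points",
    "pinch_point_analysis",
]


@dataclass
class CostDistanceField:
    grid: RasterGrid  # accumulated least cost, +inf unreachable, NaN nodata
    source_cells: np.ndarray


def _edge_cost_graph(surface: ResistanceSurface, neighbourhood: int = 8):
    """Sparse matrix of movement costs d_ij * (r_i+r_j)/2 * cell_size."""
    g = build_lattice_graph(surface, neighbourhood)
    # conductance = 1/(d*(ra+rb)/2) in cell units; cost = cell_size / conductance
    cost = surface.grid.cell_size / g.conductance
    n = g.n_nodes
    mat = coo_matrix(
        (np.concatenate([cost, cost]),
         (np.concatenate([g.edges[:, 0], g.edges[:, 1]]),
          np.concatenate([g.edges[:, 1], g.edges[:, 0]]))),
        shape=(n, n),
    ).tocsr()
    return g, mat


def cost_distance(
    surface: ResistanceSurface,
    source_rows_cols: tuple[np.ndarray, np.ndarray],
    neighbourhood: int = 8,
) -> CostDistanceField:
    """Accumulated least cost from a source core to every cell (Dijkstra
    over the lattice, edge cost d_ij * (r_i + r_j)/2 * cell_size)."""
    rr = np.atleast_1d(source_rows_cols[0])
    cc = np.atleast_1d(source_rows_cols[1])
    if rr.size == 0:
        raise ValueError("source is empty")
    g, mat = _edge_cost_graph(surface, neighbourhood)
    src_nodes = g.node_index[rr, cc]
    src_nodes = src_nodes[src_nodes >= 0]
    d = _sparse_dijkstra(mat, directed=False, indices=src_nodes, min_only=True)
    out = np.full(surface.grid.shape, np.nan)
    out[tuple(g.cells.T)] = d
    return CostDistanceField(surface.grid.like(out), np.column_stack([rr, cc]))


def least_cost_corridor(
    cwd_a: CostDistanceField, cwd_b: CostDistanceField, cutoff: float
):
    """Corridor mask and least-cost-path cost between two cores.

    The LCP cost is min over cells of cwd_a + cwd_b; the corridor is every
    cell whose summed cost stays within ``cutoff`` of it. cutoff=0 gives
    exactly the least-cost path cells; corridors are nested in the cutoff.
    """
    if not cwd_a.grid.aligned_with(cwd_b.grid):
        raise ValueError("cost fields on different grids")
    total = cwd_a.grid.data + cwd_b.grid.data
    finite = np.isfinite(total)
    if not finite.any():
        warnings.warn("cores are mutually unreachable; empty corridor")
        return np.zeros_like(total, bool), np.inf
    lcp = float(np.nanmin(total[finite]))
    mask = finite & (total <= lcp + cutoff + 1e-12)
    return mask, lcp


def corridor_current(
    surface: ResistanceSurface,
    corridor_mask: np.ndarray,
    source_rows_cols,
    target_rows_cols,
    neighbourhood: int = 8,
) -> tuple[RasterGrid, PairSolve]:
    """Circuit solve restricted to the corridor cells (cells outside the
    mask treated as nodata). Returns the per-cell current raster and the
    solve diagnostics (unreachable pairs carry infinite resistance)."""
    r = np.where(corridor_mask, surface.grid.data, np.nan)
    sub = ResistanceSurface(surface.grid.like(r), surface.epsilon, surface.provenance)
    g = build_lattice_graph(sub, neighbourhood)
    src = g.node_index[tuple(np.atleast_1d(a) for a in source_rows_cols)]
    tgt = g.node_index[tuple(np.atleast_1d(a) for a in target_rows_cols)]
    src = src[src >= 0]
    tgt = tgt[tgt >= 0]
    out = np.full(surface.grid.shape, np.nan)
    if src.size == 0 or tgt.size == 0:
        return surface.grid.like(out), PairSolve(None, None, np.inf, False)
    sol = solve_pair(g, src, tgt)
    if sol.reachable:
        out[tuple(g.cells.T)] = sol.cell_current
    return surface.grid.like(out), sol


@dataclass
class PinchPointCluster:
    cells: np.ndarray  # (n, 2) row/col
    area_m2: float
    max_current: float
    mean_current: float
    pair: tuple[int, int] | None = None


def extract_pinch_points(
    current: RasterGrid,
    percentile: float = 99.0,
    min_cells: int = 2,
    pair: tuple[int, int] | None = None,
) -> list[PinchPointCluster]:
    """Clusters of >= min_cells queen-adjacent cells in the top
    (100-percentile)% of finite current values.

    The threshold is the stated percentile of the finite values (cells >=
    threshold qualify); with fewer than 100 finite cells the percentile is
    unstable and a warning is raised; an all-constant raster yields no
    clusters.
    """
    vals = current.data[np.isfinite(current.data)]
    if vals.size == 0:
        return []
    if vals.size < 100:
        warnings.warn("fewer than 100 finite cells; percentile threshold unstable")
    if np.ptp(vals) == 0:
        warnings.warn("constant current raster; no pinch points")
        return []
    thr = float(np.percentile(vals, percentile))
    mask = np.isfinite(current.data) & (current.data >= thr)
    lab, n = ndimage.label(mask, structure=QUEEN)
    clusters = []
    cell_area = current.cell_size**2
    for g in range(1, n + 1):
        cells = np.argwhere(lab == g)
        if len(cells) < min_cells:
            continue
        cur = current.data[tuple(cells.T)]
        clusters.append(
            PinchPointCluster(
                cells=cells,
                area_m2=float(len(cells) * cell_area),
                max_current=float(cur.max()),
                mean_current=float(cur.mean()),
                pair=pair,
            )
        )
    return clusters


def pinch_point_analysis(
    surface: ResistanceSurface,
    combined: RasterGrid,
    tau_critical: float = 0.9,
    corridor_cutoff: float | None = None,
    percentile: float = 99.0,
    min_cells: int = 2,
    link_dist_m: float = 300.0,
    neighbourhood: int = 8,
):
    """Full pinch-point workflow between critical core areas.

    Critical cores are delineated at ``tau_critical`` with the same
    grouping rule as ordinary cores. For every core pair the least-cost
    corridor is cut at ``corridor_cutoff`` (default: 5 crossing costs at
    the mean landscape resistance), the circuit is solved inside it, and
    top-percentile current clusters are extracted per pair and merged by
    union into one reported set.

    Returns (clusters, critical cores, merged current raster).
    """
    cores = delineate_core_areas(
        combined, tau=tau_critical, min_cells=min_cells, link_dist_m=link_dist_m,
        isolated="keep",
    )
    if cores.n_groups < 2:
        warnings.warn("fewer than 2 critical core areas; no pinch points")
        return [], cores, combined.like(np.full(combined.shape, np.nan))
    if corridor_cutoff is None:
        mean_r = float(np.nanmean(surface.grid.data))
        corridor_cutoff = 5.0 * mean_r * surface.grid.cell_size

    cwd = {g: cost_distance(surface, cores.cells(g), neighbourhood) for g in cores.group_ids}
    merged_current = np.full(combined.shape, np.nan)
    union_cells = set()
    clusters_all = []
    for a, b in combinations(cores.group_ids, 2):
        mask, lcp = least_cost_corridor(cwd[a], cwd[b], corridor_cutoff)
        if not np.isfinite(lcp) or mask.sum() < 2:
            continue
        cur, sol = corridor_current(surface, mask, cores.cells(a), cores.cells(b), neighbourhood)
        if not sol.reachable:
            continue
        ok = np.isfinite(cur.data)
        merged_current[ok] = np.fmax(
            np.where(np.isfinite(merged_current[ok]), merged_current[ok], 0.0), cur.data[ok]
        )
        for cl in extract_pinch_points(cur, percentile, min_cells, pair=(a, b)):
            key = frozenset(map(tuple, cl.cells.tolist()))
            if key not in union_cells:
                union_cells.add(key)
                clusters_all.append(cl)
    # merge overlapping per-pair clusters by union flood-fill
    if clusters_all:
        mask = np.zeros(combined.shape, bool)
        for cl in clusters_all:
            mask[tuple(cl.cells.T)] = True
        lab, n = ndimage.label(mask, structure=QUEEN)
        merged = []
        cell_area = combined.cell_size**2
        for g in range(1, n + 1):
            cells = np.argwhere(lab == g)
            if len(cells) < min_cells:
                continue
            cur = merged_current[tuple(cells.T)]
            cur = cur[np.isfinite(cur)]
            merged.append(
                PinchPointCluster(
                    cells=cells,
                    area_m2=float(len(cells) * cell_area),
                    max_current=float(cur.max()) if cur.size else np.nan,
                    mean_current=float(cur.mean()) if cur.size else np.nan,
                )
            )
        clusters_all = merged
    return clusters_all, cores, combined.like(merged_current)
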
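"""Circuit-theory connectivity on a raster resistance surface.

The combined suitability map is inverted into a movement-resistance
surface (r = 1/max(s, eps)); contiguous high-suitability cell groups act
as circuit nodes ("core areas"); and movement is modelled as a random walk
on the lattice of valid cells: every cell is a node, every pair of queen
neighbours an edge whose conductance is the reciprocal of the mean of the
two cell resistances times the centre-to-centre distance (1 for
orthogonal, sqrt(2) for diagonal, in cell units). For each pair of core
areas one unit of current is injected and the Kirchhoff system L v = i is
solved with the cores collapsed to supernodes; per-cell current (half the
sum of absolute incident edge currents) accumulated over all pairs gives
the cumulative current map, and the voltage difference between the
terminals is the pair's effective resistance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.linalg import splu

from .grid import RasterGrid

__all__ = [
    "ResistanceSurface",
    "CoreAreaSet",
    "LatticeGraph",
    "CurrentMap",
    "suitability_to_resistance",
    "delineate_core_areas",
    "build_lattice_graph",
    "solve_pair",
    "cumulative_current",
]

QUEEN = np.ones((3, 3), dtype=int)
ROOK = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


@dataclass
class ResistanceSurface:
    grid: RasterGrid
    epsilon: float
    provenance: str = "inverse-suitability"


def suitability_to_resistance(
    combined: RasterGrid, epsilon: float = 1e-3, mode: str = "inverse"
) -> ResistanceSurface:
    """Movement resistance from suitability.

    ``inverse``: r = 1/max(s, eps) (multiplicative inverse with a floor so
    unsuitable cells stay finite). ``complement``: r = (1 - s) + eps.
    Nodata propagates.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    s = combined.data
    if np.nanmin(s) < -1e-9 or np.nanmax(s) > 1 + 1e-9:
        raise ValueError("suitability must lie in [0,1]")
    if mode == "inverse":
        r = 1.0 / np.maximum(s, epsilon)
    elif mode == "complement":
        r = (1.0 - s) + epsilon
    else:
        raise ValueError(f"unknown resistance mode {mode!r}")
    r = np.where(combined.valid, r, np.nan)
    return ResistanceSurface(combined.like(r), epsilon, f"{mode}-suitability")


@dataclass
class CoreAreaSet:
    """Labelled groups of high-suitability cells used as circuit nodes."""

    labels: np.ndarray  # 0 = background, 1..n = group id
    n_groups: int
    tau: float
    min_cells: int
    link_dist_m: float
    grid: RasterGrid
    dropped_isolated: list[int] = field(default_factory=list)

    def cells(self, group: int) -> tuple[np.ndarray, np.ndarray]:
        return np.nonzero(self.labels == group)

    @property
    def group_ids(self) -> list[int]:
        return [g for g in range(1, self.n_groups + 1)]

    def area_km2(self) -> float:
        return float(np.count_nonzero(self.labels) * self.grid.cell_size**2 / 1e6)


def delineate_core_areas(
    combined: RasterGrid,
    tau: float = 0.5,
    min_cells: int = 2,
    link_dist_m: float = 300.0,
    adjacency: str = "queen",
    isolated: str = "filter",
) -> CoreAreaSet:
    """Delineate core areas: cells with suitability >= tau, grouped by
    queen adjacency, groups below ``min_cells`` dropped, and groups whose
    nearest other group (minimum centre-to-centre cell distance) is
    farther than ``link_dist_m`` removed (``isolated='filter'``) — the
    300 m default being the smallest maximum dispersal distance among the
    focal species. ``isolated='keep'`` retains them.
    """
    structure = QUEEN if adjacency == "queen" else ROOK
    mask = combined.valid & (combined.data >= tau)
    lab, n = ndimage.label(mask, structure=structure)
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    keep = [g for g, s in zip(range(1, n + 1), sizes) if s >= min_cells]
    X, Y = combined.cell_centers()
    centers = {g: (X[lab == g], Y[lab == g]) for g in keep}

    dropped = []
    if isolated == "filter" and len(keep) > 1:
        survivors = []
        for g in keep:
            gx, gy = centers[g]
            near = False
            for h in keep:
                if h == g:
                    continue
                hx, hy = centers[h]
                d2 = (gx[:, None] - hx[None, :]) ** 2 + (gy[:, None] - hy[None, :]) ** 2
                if d2.min() <= link_dist_m**2 + 1e-9:
                    near = True
                    break
            if near:
                survivors.append(g)
            else:
                dropped.append(g)
        keep = survivors
    if not keep:
        warnings.warn("no qualifying core area")

    out = np.zeros_like(lab)
    for new_id, g in enumerate(keep, start=1):
        out[lab == g] = new_id
    return CoreAreaSet(
        labels=out,
        n_groups=len(keep),
        tau=tau,
        min_cells=min_cells,
        link_dist_m=link_dist_m,
        grid=combined,
        dropped_isolated=dropped,
    )


@dataclass
class LatticeGraph:
    """Weighted conductance graph over valid raster cells."""

    grid: RasterGrid
    node_index: np.ndarray  # cell -> node id, -1 for nodata
    cells: np.ndarray  # node id -> (row, col)
    edges: np.ndarray  # (m, 2) node pairs
    conductance: np.ndarray  # (m,)
    component: np.ndarray  # node id -> component label

    @property
    def n_nodes(self) -> int:
        return len(self.cells)


def build_lattice_graph(surface: ResistanceSurface, neighbourhood: int = 8) -> LatticeGraph:
    """Lattice graph of valid cells; edge conductance between neighbours
    i,j is 1 / (d_ij * (r_i + r_j)/2) with d_ij in cell units (1
    orthogonal, sqrt(2) diagonal)."""
    r = surface.grid.data
    valid = surface.grid.valid
    if valid.sum() < 2:
        raise ValueError("need at least 2 valid cells")
    if np.nanmin(r) <= 0:
        raise ValueError("resistances must be positive")
    n_rows, n_cols = r.shape
    node_index = np.full(r.shape, -1, dtype=int)
    cells = np.argwhere(valid)
    node_index[valid] = np.arange(len(cells))

    if neighbourhood == 8:
        offsets = [(0, 1, 1.0), (1, 0, 1.0), (1, 1, np.sqrt(2)), (1, -1, np.sqrt(2))]
    elif neighbourhood == 4:
        offsets = [(0, 1, 1.0), (1, 0, 1.0)]
    else:
        raise ValueError("neighbourhood must be 4 or 8")

    e_i, e_j, g = [], [], []
    for di, dj, d in offsets:
        r0 = slice(max(0, -di), n_rows - max(0, di))
        c0 = slice(max(0, -dj), n_cols - max(0, dj))
        r1 = slice(max(0, di), n_rows - max(0, -di))
        c1 = slice(max(0, dj), n_cols - max(0, -dj))
        a = node_index[r0, c0]
        b = node_index[r1, c1]
        ra = r[r0, c0]
        rb = r[r1, c1]
        ok = (a >= 0) & (b >= 0)
        e_i.append(a[ok])
        e_j.append(b[ok])
        g.append(1.0 / (d * (ra[ok] + rb[ok]) / 2.0))
    edges = np.column_stack([np.concatenate(e_i), np.concatenate(e_j)])
    cond = np.concatenate(g)

    n = len(cells)
    adj = csr_matrix(
        (np.ones(len(edges) * 2), (np.concatenate([edges[:, 0], edges[:, 1]]),
                                   np.concatenate([edges[:, 1], edges[:, 0]]))),
        shape=(n, n),
    )
    from scipy.sparse.csgraph import connected_components

    _, comp = connected_components(adj, directed=False)
    return LatticeGraph(surface.grid, node_index, cells, edges, cond, comp)


@dataclass
class PairSolve:
    voltages: np.ndarray | None  # per node, None if unreachable
    cell_current: np.ndarray | None  # per node
    effective_resistance: float
    reachable: bool


def _collapse(graph: LatticeGraph, groups: list[np.ndarray]):
    """Merge each group of node ids into one supernode; returns the mapping
    old node -> merged node and merged edge arrays (conductances summed,
    self-loops dropped)."""
    n = graph.n_nodes
    mapping = np.arange(n)
    merged_ids = []
    next_free = n
    for g in groups:
        mapping[g] = next_free
        merged_ids.append(next_free)
        next_free += 1
    uniq, node_of = np.unique(mapping, return_inverse=True)
    e_a = node_of[graph.edges[:, 0]]
    e_b = node_of[graph.edges[:, 1]]
    keep = e_a != e_b
    lut = {int(v): i for i, v in enumerate(uniq)}
    reps = [lut[int(r)] for r in merged_ids]
    return node_of, len(uniq), (e_a[keep], e_b[keep], graph.conductance[keep]), reps


def solve_pair(
    graph: LatticeGraph,
    source_cells: np.ndarray,
    target_cells: np.ndarray,
    injection: float = 1.0,
) -> PairSolve:
    """Inject ``injection`` units of current at the source core and draw
    it from the target core; solve for node voltages, per-cell current and
    the effective resistance between the cores.

    Core cells are short-circuited into supernodes. If the cores fall in
    different graph components the pair is reported unreachable with
    infinite effective resistance.
    """
    src = np.asarray(source_cells, int)
    tgt = np.asarray(target_cells, int)
    if src.size == 0 or tgt.size == 0:
        raise ValueError("source and target must be non-empty")
    if np.intersect1d(src, tgt).size:
        raise ValueError("source and target overlap")
    if graph.component[src[0]] != graph.component[tgt[0]]:
        return PairSolve(None, None, np.inf, False)

    node_of, n_merged, (ea, eb, g), (s_node, t_node) = _collapse(graph, [src, tgt])
    # Laplacian of the merged graph
    rows = np.concatenate([ea, eb, ea, eb])
    cols = np.concatenate([eb, ea, ea, eb])
    vals = np.concatenate([-g, -g, g, g])
    L = coo_matrix((vals, (rows, cols)), shape=(n_merged, n_merged)).tocsr()

    # restrict to the component containing the terminals
    from scipy.sparse.csgraph import connected_components

    _, comp = connected_components(L != 0, directed=False)
    in_comp = comp == comp[s_node]
    idx = np.flatnonzero(in_comp)
    pos = {int(v): i for i, v in enumerate(idx)}
    Lc = L[np.ix_(idx, idx)]
    s_c, t_c = pos[int(s_node)], pos[int(t_node)]

    # ground the target: delete its row/column
    keep = np.ones(len(idx), bool)
    keep[t_c] = False
    Lg = Lc[np.ix_(np.flatnonzero(keep), np.flatnonzero(keep))].tocsc()
    rhs = np.zeros(len(idx) - 1)
    s_g = s_c - (1 if s_c > t_c else 0)
    rhs[s_g] = injection
    v_red = splu(Lg).solve(rhs)
    v = np.zeros(len(idx))
    v[keep] = v_red  # grounded node at 0

    voltages = np.full(n_merged, np.nan)
    voltages[idx] = v
    v_nodes = voltages[node_of]  # per original node

    # per-cell current: half the sum of |I| over incident edges
    dv = v_nodes[graph.edges[:, 0]] - v_nodes[graph.edges[:, 1]]
    i_edge = graph.conductance * dv
    cur = np.zeros(graph.n_nodes)
    np.add.at(cur, graph.edges[:, 0], np.abs(i_edge))
    np.add.at(cur, graph.edges[:, 1], np.abs(i_edge))
    cur *= 0.5
    # terminal cells carry the full injected current by convention; exclude
    cur[src] = 0.0
    cur[tgt] = 0.0
    r_eff = float(v_nodes[src[0]] - v_nodes[tgt[0]])
    return PairSolve(v_nodes, cur, r_eff, True)


def kirchhoff_residual(graph: LatticeGraph, solve: PairSolve,
                       source_cells, target_cells) -> dict:
    """Diagnostics: max |net current| at non-terminal nodes and the net
    flux out of the source supernode."""
    v = solve.voltages
    dv = v[graph.edges[:, 0]] - v[graph.edges[:, 1]]
    i_edge = graph.conductance * dv
    net = np.zeros(graph.n_nodes)
    np.add.at(net, graph.edges[:, 0], -i_edge)
    np.add.at(net, graph.edges[:, 1], i_edge)
    terminals = np.concatenate([np.asarray(source_cells), np.asarray(target_cells)])
    mask = np.ones(graph.n_nodes, bool)
    mask[terminals] = False
    mask &= np.isfinite(v)
    return {
        "max_net_nonterminal": float(np.max(np.abs(net[mask]))) if mask.any() else 0.0,
        "source_flux": float(-net[np.asarray(source_cells)].sum()),
    }


@dataclass
class CurrentMap:
    grid: RasterGrid  # cumulative current per cell
    pair_resistance: dict  # (i, j) core ids -> effective resistance
    injection: float = 1.0


def cumulative_current(
    surface: ResistanceSurface,
    cores: CoreAreaSet,
    pairs=None,
    neighbourhood: int = 8,
    injection: float = 1.0,
) -> CurrentMap:
    """Sum per-cell current over (by default all) unordered core pairs.

    Cells belonging to the active pair's cores are excluded from that
    pair's contribution; unreachable pairs record infinite effective
    resistance and add nothing.
    """
    if cores.n_groups < 2:
        raise ValueError("need >= 2 core areas as circuit nodes")
    graph = build_lattice_graph(surface, neighbourhood)
    group_nodes = {}
    for gid in cores.group_ids:
        rr, cc = cores.cells(gid)
        nodes = graph.node_index[rr, cc]
        group_nodes[gid] = nodes[nodes >= 0]
    if pairs is None:
        pairs = list(combinations(cores.group_ids, 2))
    total = np.zeros(graph.n_nodes)
    r_eff = {}
    for a, b in pairs:
        na, nb = group_nodes[a], group_nodes[b]
        if na.size == 0 or nb.size == 0:
            r_eff[(a, b)] = np.inf
            continue
        sol = solve_pair(graph, na, nb, injection)
        r_eff[(a, b)] = sol.effective_resistance
        if sol.reachable:
            total += sol.cell_current
    out = np.full(surface.grid.shape, np.nan)
    out[tuple(graph.cells.T)] = total
    out = np.where(surface.grid.valid, out, np.nan)
    return CurrentMap(surface.grid.like(out), r_eff, injection)
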
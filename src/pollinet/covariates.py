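"""Analysis-grid predictor stack: focal proportions and means, z-scoring,
and Spearman collinearity screening.

Environmental predictors are summarised over a circular neighbourhood of
the analysis-cell centre (default radius 100 m): land-cover classes as the
proportion of fine cells in the disc belonging to the class, continuous
rasters as the disc mean with an optional square-root transform applied
*after* averaging. A fine cell belongs to the disc when its centre lies
within the radius of the analysis-cell centre (the centre cell is always
included); at the grid edge only in-grid cells are counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .grid import RasterGrid, check_aligned

__all__ = [
    "PredictorStack",
    "focal_proportion",
    "focal_mean",
    "standardise",
    "correlation_screen",
]

#: Screening preference: garden is retained ahead of the impervious and
#: population layers it tends to correlate with in urban landscapes.
DEFAULT_KEEP_PREFERENCE = (
    "garden",
    "wood",
    "wet",
    "arable",
    "grass",
    "allot",
    "alt",
    "imperv",
    "popdensity",
)


@dataclass
class PredictorStack:
    """Named, aligned predictor layers with their standardisation constants.

    ``constants[name] = (mean, sd)`` is populated by :func:`standardise`
    and applied unchanged when scoring new points or grids.
    """

    layers: dict[str, RasterGrid]
    constants: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        grids = list(self.layers.values())
        if grids:
            check_aligned(*grids)

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def grid(self) -> RasterGrid:
        return next(iter(self.layers.values()))

    def values_at(self, x, y) -> dict[str, np.ndarray]:
        return {name: g.value_at(x, y) for name, g in self.layers.items()}

    def subset(self, names) -> "PredictorStack":
        return PredictorStack(
            {n: self.layers[n] for n in names},
            {n: self.constants[n] for n in names if n in self.constants},
        )


def _disc_offsets(fine: RasterGrid, analysis: RasterGrid, radius_m: float):
    """Fine-cell offsets (relative to the top-left fine cell under an
    analysis cell) whose centres fall within radius_m of the analysis-cell
    centre."""
    f = analysis.cell_size / fine.cell_size
    if abs(f - round(f)) > 1e-9:
        raise ValueError("fine cell size must divide analysis cell size")
    f = int(round(f))
    # centre of analysis cell sits (f-1)/2 fine cells from the block's
    # top-left fine-cell centre, in fine-cell units
    half = (f - 1) / 2.0
    r_cells = radius_m / fine.cell_size
    span = int(np.ceil(r_cells - min(half, 0) + half)) + 1
    offs = []
    for di in range(-span, span + f):
        for dj in range(-span, span + f):
            if ((di - half) ** 2 + (dj - half) ** 2) <= r_cells**2 + 1e-12:
                offs.append((di, dj))
    return f, offs


def _focal_sums(values: np.ndarray, fine: RasterGrid, analysis: RasterGrid, radius_m: float):
    """Disc sum and valid-cell count of ``values`` for every analysis cell."""
    f, offs = _disc_offsets(fine, analysis, radius_m)
    n_ar, n_ac = analysis.shape
    if fine.n_rows < n_ar * f or fine.n_cols < n_ac * f:
        raise ValueError("fine raster does not cover the analysis extent")
    pad = max(abs(o) for off in offs for o in off) + 1
    padded = np.pad(values.astype(float), pad, constant_values=np.nan)
    total = np.zeros((n_ar, n_ac))
    count = np.zeros((n_ar, n_ac))
    base_i = pad + np.arange(n_ar) * f
    base_j = pad + np.arange(n_ac) * f
    for di, dj in offs:
        block = padded[np.ix_(base_i + di, base_j + dj)]
        ok = np.isfinite(block)
        total += np.where(ok, block, 0.0)
        count += ok
    return total, count


def focal_proportion(
    fine: RasterGrid,
    class_set,
    analysis: RasterGrid,
    radius_m: float = 100.0,
) -> RasterGrid:
    """Proportion of fine land-cover cells in ``class_set`` within
    ``radius_m`` of each analysis-cell centre. Cells whose whole disc is
    nodata become nodata."""
    class_set = {float(c) for c in np.atleast_1d(list(class_set))}
    member = np.where(fine.valid, np.isin(fine.data, list(class_set)).astype(float), np.nan)
    total, count = _focal_sums(member, fine, analysis, radius_m)
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = np.where(count > 0, total / count, np.nan)
    return analysis.like(prop)


def focal_mean(
    raster: RasterGrid,
    analysis: RasterGrid,
    radius_m: float = 100.0,
    transform: str = "identity",
) -> RasterGrid:
    """Disc mean of a continuous raster, with an optional transform applied
    after averaging (``sqrt`` approximates normality for right-skewed
    nonnegative inputs such as altitude)."""
    if transform not in ("identity", "sqrt"):
        raise ValueError(f"unknown transform {transform!r}")
    if transform == "sqrt" and np.nanmin(raster.data) < 0:
        raise ValueError("sqrt transform requires nonnegative input")
    total, count = _focal_sums(raster.data, raster, analysis, radius_m)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(count > 0, total / count, np.nan)
    if transform == "sqrt":
        mean = np.sqrt(mean)
    return analysis.like(mean)


def standardise(stack: PredictorStack) -> PredictorStack:
    """Z-score every layer over its valid cells (sample sd, ddof=1), storing
    the constants so the identical transform can be applied to new data.

    Re-standardising an already standardised stack is the identity up to
    floating point.
    """
    out_layers: dict[str, RasterGrid] = {}
    constants: dict[str, tuple[float, float]] = {}
    for name, g in stack.layers.items():
        vals = g.data[g.valid]
        if vals.size < 2:
            raise ValueError(f"layer {name!r} has too few valid cells to standardise")
        mu = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1))
        if sd == 0:
            raise ValueError(f"layer {name!r} is constant; cannot standardise")
        out_layers[name] = g.like((g.data - mu) / sd)
        constants[name] = (mu, sd)
    return PredictorStack(out_layers, constants)


def correlation_screen(
    stack: PredictorStack,
    x,
    y,
    rho_threshold: float = 0.7,
    keep_preference=DEFAULT_KEEP_PREFERENCE,
):
    """Drop collinear predictors by Spearman rank correlation at the model
    points.

    Layers with |rho| above the threshold are grouped transitively (graph
    components over the exceedance matrix) and, within each group, only the
    layer appearing earliest in ``keep_preference`` is retained — so a
    chain A~B~C keeps a single layer even if A and C are not themselves
    correlated, matching the practice of dropping all but one of a mutually
    entangled set.

    Returns
    -------
    retained : list of layer names, in stack order
    rho : pandas-style dict-of-dicts Spearman matrix over all layers
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ValueError("need at least 3 points for a rank correlation")
    names = stack.names
    pref = list(keep_preference) + [n for n in names if n not in keep_preference]
    if len(set(pref)) != len(pref):
        raise ValueError("keep_preference must be a total order without repeats")
    rank = {n: pref.index(n) for n in names}

    vals = {n: stack.layers[n].value_at(x, y) for n in names}
    p = len(names)
    rho = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            a, b = vals[names[i]], vals[names[j]]
            ok = np.isfinite(a) & np.isfinite(b)
            r = stats.spearmanr(a[ok], b[ok]).statistic if ok.sum() >= 3 else 0.0
            rho[i, j] = rho[j, i] = 0.0 if np.isnan(r) else r

    # transitive grouping: union-find over the exceedance graph
    parent = list(range(p))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(p):
        for j in range(i + 1, p):
            if abs(rho[i, j]) > rho_threshold:
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(p):
        groups.setdefault(find(i), []).append(i)
    keep = set()
    for members in groups.values():
        keep.add(min(members, key=lambda i: rank[names[i]]))
    retained = [n for i, n in enumerate(names) if i in keep]
    rho_dict = {
        names[i]: {names[j]: float(rho[i, j]) for j in range(p)} for i in range(p)
    }
    return retained, rho_dict
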
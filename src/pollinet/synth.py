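"""Synthetic landscapes, occurrence records and planner-style corridor
polygons with known ground truth.

Every downstream stage of the pipeline (record filtering, background
sampling, suitability fitting, connectivity, corridor comparison) is
exercised against data generated here, where the generating suitability
function, the observer-bias surface and the exact contamination injected
into the records are all known. That makes closed-loop tests possible: the
filter audit can be compared against the contamination ledger, and fitted
models against the generating linear predictor.

The land-cover field emulates an urban mosaic: one latent Gaussian random
field per class with a stated correlation length, each cell taking the
class whose (offset-calibrated) field is largest, so class fractions track
the requested weights while patches stay spatially coherent. Observer bias
is a kernel-density bump around a few "city centre" points, mimicking the
tendency of citizen-science records to cluster in accessible, populated
places.

All randomness flows from the scenario's single integer seed through
numpy's seed-sequence spawning, so identical scenarios give bit-identical
outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage

from .grid import RasterGrid
from . import covariates as cov

__all__ = [
    "SyntheticScenario",
    "generate_landscape",
    "true_suitability",
    "generate_occurrences",
    "generate_planner_corridors",
]

LAND_CLASSES = ("wood", "wet", "arable", "grass", "garden", "allot", "imperv")
CLASS_CODES = {name: float(i) for i, name in enumerate(LAND_CLASSES)}

#: Generating smooth effects per species: predictor -> (linear, quadratic)
#: coefficients on the raw focal proportion / transformed scale. Chosen to
#: mimic generalist pollinators with distinct but overlapping preferences.
DEFAULT_TRUE_COEFFICIENTS = {
    "bombus": {
        "intercept": -3.2,
        "grass": (7.0, -3.5),
        "garden": (5.0, 0.0),
        "wood": (4.0, -5.0),
        "alt": (-0.8, 0.0),
    },
    "meadow_brown": {
        "intercept": -3.4,
        "grass": (9.0, -4.5),
        "arable": (4.0, -4.0),
        "wood": (2.5, 0.0),
        "alt": (-0.5, 0.0),
    },
    "ringlet": {
        "intercept": -3.6,
        "wood": (7.0, -2.5),
        "wet": (5.0, 0.0),
        "grass": (5.0, -2.5),
        "alt": (1.0, 0.0),
    },
}


@dataclass
class SyntheticScenario:
    """Parameters of one synthetic study system.

    Defaults describe a 6.4 km square city fragment on a 10 m land-cover
    grid analysed at 100 m, with three pollinator-like species of 200
    presences each and mild record contamination.
    """

    seed: int = 0
    extent: tuple[float, float] = (6400.0, 6400.0)
    fine_res: float = 10.0
    analysis_res: float = 100.0
    class_weights: dict[str, float] = field(
        default_factory=lambda: {
            "wood": 0.15,
            "wet": 0.05,
            "arable": 0.10,
            "grass": 0.25,
            "garden": 0.15,
            "allot": 0.05,
            "imperv": 0.25,
        }
    )
    smoothness: float = 300.0  # correlation length, metres
    n_presence_per_species: int = 200
    bias_strength: float = 1.0
    contamination: dict[str, float] = field(
        default_factory=lambda: {
            "duplicate": 0.05,
            "uncertain": 0.03,
            "undated": 0.02,
            "out_of_year": 0.02,
        }
    )
    year_range: tuple[int, int] = (2015, 2022)
    true_coefficients: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_TRUE_COEFFICIENTS.items()}
    )

    def __post_init__(self) -> None:
        if self.extent[0] <= 0 or self.extent[1] <= 0:
            raise ValueError("extent must be positive")
        if self.fine_res <= 0 or self.analysis_res <= 0:
            raise ValueError("resolutions must be positive")
        ratio = self.analysis_res / self.fine_res
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("fine_res must divide analysis_res")
        total = sum(self.class_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_weights must sum to 1 (got {total})")
        for name, frac in self.contamination.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"contamination fraction {name} outside [0,1]")

    @property
    def species(self) -> list[str]:
        return list(self.true_coefficients)

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one named stream of the scenario."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


# stream ids for the scenario's seed tree
_STREAM_LANDSCAPE = 1
_STREAM_OCCURRENCE = 2
_STREAM_CENTRES = 3


def _gaussian_field(rng, shape, sigma_cells):
    """Unit-variance Gaussian random field with ~sigma_cells correlation."""
    white = rng.standard_normal(shape)
    if sigma_cells > 0:
        f = ndimage.gaussian_filter(white, sigma_cells, mode="wrap")
    else:
        f = white
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_landscape(scenario: SyntheticScenario):
    """Generate the landscape rasters.

    Returns
    -------
    landcover : RasterGrid
        Categorical classes (codes per :data:`CLASS_CODES`) at fine
        resolution.
    elevation : RasterGrid
        Metres above a reference, >= 0, at fine resolution.
    population : RasterGrid
        People per hectare, >= 0, at fine resolution, peaked around the
        synthetic city centres.
    """
    rng = scenario.rng(_STREAM_LANDSCAPE)
    n_rows = int(round(scenario.extent[1] / scenario.fine_res))
    n_cols = int(round(scenario.extent[0] / scenario.fine_res))
    sigma = scenario.smoothness / scenario.fine_res
    names = [n for n, w in scenario.class_weights.items() if w > 0]
    weights = np.array([scenario.class_weights[n] for n in names])

    fields = np.stack([_gaussian_field(rng, (n_rows, n_cols), sigma) for _ in names])
    # calibrate per-class offsets so argmax fractions track the weights
    offsets = np.log(weights / weights.mean())
    for _ in range(60):
        labels = np.argmax(fields + offsets[:, None, None], axis=0)
        frac = np.bincount(labels.ravel(), minlength=len(names)) / labels.size
        err = weights - frac
        if np.abs(err).max() < 0.002:
            break
        offsets += 1.5 * err
    labels = np.argmax(fields + offsets[:, None, None], axis=0)
    codes = np.array([CLASS_CODES[n] for n in names])
    landcover = RasterGrid(codes[labels], scenario.fine_res)

    elev_field = _gaussian_field(rng, (n_rows, n_cols), 2 * sigma)
    elevation = RasterGrid(np.maximum(60.0 + 40.0 * elev_field, 0.0), scenario.fine_res)

    centres = _city_centres(scenario)
    X, Y = landcover.cell_centers()
    dens = np.zeros((n_rows, n_cols))
    scale = 0.25 * min(scenario.extent)
    for cx, cy in centres:
        dens += np.exp(-((X - cx) ** 2 + (Y - cy) ** 2) / (2 * scale**2))
    pop_noise = np.exp(0.5 * _gaussian_field(rng, (n_rows, n_cols), sigma))
    population = RasterGrid(40.0 * dens * pop_noise, scenario.fine_res)
    return landcover, elevation, population


def _city_centres(scenario: SyntheticScenario, n: int = 3) -> np.ndarray:
    rng = scenario.rng(_STREAM_CENTRES)
    w, h = scenario.extent
    return np.column_stack(
        [rng.uniform(0.2 * w, 0.8 * w, n), rng.uniform(0.2 * h, 0.8 * h, n)]
    )


def analysis_grid(scenario: SyntheticScenario) -> RasterGrid:
    """Empty grid at the analysis resolution covering the extent."""
    n_rows = int(round(scenario.extent[1] / scenario.analysis_res))
    n_cols = int(round(scenario.extent[0] / scenario.analysis_res))
    return RasterGrid(np.zeros((n_rows, n_cols)), scenario.analysis_res)


def true_predictors(scenario, landcover, elevation, population) -> cov.PredictorStack:
    """Raw (unstandardised) focal predictor stack used by the generating
    suitability function."""
    grid = analysis_grid(scenario)
    layers = {
        name: cov.focal_proportion(landcover, [CLASS_CODES[name]], grid)
        for name in LAND_CLASSES
    }
    layers["alt"] = cov.focal_mean(elevation, grid, transform="sqrt")
    layers["popdensity"] = cov.focal_mean(population, grid)
    return cov.PredictorStack(layers)


def _eval_linear_predictor(coeffs: dict, predictors: dict[str, np.ndarray]) -> np.ndarray:
    eta = np.full_like(next(iter(predictors.values())), float(coeffs.get("intercept", 0.0)))
    for name, c in coeffs.items():
        if name == "intercept":
            continue
        if name not in predictors:
            raise KeyError(f"predictor {name!r} not available")
        lin, quad = c
        p = predictors[name]
        # altitude enters on a scale comparable to proportions
        if name == "alt":
            p = p / 10.0
        eta = eta + lin * p + quad * p**2
    return eta


def true_suitability(
    landcover: RasterGrid,
    elevation: RasterGrid,
    population: RasterGrid,
    true_coefficients: dict,
    species: str,
    scenario: SyntheticScenario | None = None,
    predictors: cov.PredictorStack | None = None,
) -> RasterGrid:
    """Ground-truth suitability in [0,1]: inverse logit of the known
    additive function of the focal predictors."""
    if species not in true_coefficients:
        raise KeyError(f"no generating coefficients for species {species!r}")
    if predictors is None:
        if scenario is None:
            raise ValueError("need either a scenario or a precomputed predictor stack")
        predictors = true_predictors(scenario, landcover, elevation, population)
    vals = {n: g.data for n, g in predictors.layers.items()}
    eta = _eval_linear_predictor(true_coefficients[species], vals)
    return predictors.grid.like(1.0 / (1.0 + np.exp(-eta)))


def bias_surface(scenario: SyntheticScenario, grid: RasterGrid) -> RasterGrid:
    """Observer-bias surface: a KDE-style bump around the city centres,
    scaled by bias_strength (0 gives a flat surface)."""
    X, Y = grid.cell_centers()
    out = np.ones(grid.shape)
    if scenario.bias_strength > 0:
        scale = 0.2 * min(scenario.extent)
        bump = np.zeros(grid.shape)
        for cx, cy in _city_centres(scenario):
            bump += np.exp(-((X - cx) ** 2 + (Y - cy) ** 2) / (2 * scale**2))
        bump /= bump.max()
        out = 1.0 + scenario.bias_strength * bump
    return grid.like(out)


def generate_occurrences(
    scenario: SyntheticScenario,
    suitability: dict[str, RasterGrid],
    bias: RasterGrid | None = None,
):
    """Sample presence records and inject known contamination.

    Presences are drawn over analysis cells with probability proportional
    to (true suitability x bias surface), then jittered uniformly within
    the cell. Clean records carry a year uniform over the scenario's year
    range and a coordinate uncertainty of 10-50 m. Contamination rows are
    appended with exactly one defect each — an exact duplicate of a clean
    row, an uncertainty above 100 m, a missing year, or a year outside the
    range — and their exact counts are returned as a ledger.

    Returns
    -------
    table : pandas.DataFrame
        Columns species, x, y, year, uncertainty_m, is_presence.
    ledger : dict
        Per-defect injected counts plus n_clean.
    """
    rng = scenario.rng(_STREAM_OCCURRENCE)
    first = next(iter(suitability.values()))
    if bias is None:
        bias = bias_surface(scenario, first)
    rows = []
    n = scenario.n_presence_per_species
    y0, y1 = scenario.year_range
    for sp, suit in suitability.items():
        if np.nanmin(suit.data) < -1e-9 or np.nanmax(suit.data) > 1 + 1e-9:
            raise ValueError("suitability must lie in [0,1]")
        w = np.where(suit.valid, suit.data * bias.data, 0.0).ravel()
        if n > np.count_nonzero(w):
            raise ValueError("requested more presences than cells with positive weight")
        w = w / w.sum()
        cells = rng.choice(w.size, size=n, replace=True, p=w)
        r, c = np.unravel_index(cells, suit.shape)
        X, Y = suit.cell_centers()
        jit = (rng.random((n, 2)) - 0.5) * suit.cell_size
        xs = X[r, c] + jit[:, 0]
        ys = Y[r, c] + jit[:, 1]
        years = rng.integers(y0, y1 + 1, n)
        unc = rng.uniform(10, 50, n)
        for i in range(n):
            rows.append((sp, xs[i], ys[i], float(years[i]), unc[i], True))
    clean = pd.DataFrame(
        rows, columns=["species", "x", "y", "year", "uncertainty_m", "is_presence"]
    )
    # clean rows must be unique on the dedup key; cell jitter makes exact
    # coordinate collisions measure-zero, but guard anyway
    clean = clean.drop_duplicates(["species", "x", "y", "year"]).reset_index(drop=True)

    n_clean = len(clean)
    ledger = {"n_clean": n_clean}
    contaminated = [clean]
    frac = scenario.contamination
    counts = {k: int(round(frac.get(k, 0.0) * n_clean)) for k in
              ("duplicate", "uncertain", "undated", "out_of_year")}

    if counts["duplicate"]:
        idx = rng.choice(n_clean, counts["duplicate"], replace=False)
        contaminated.append(clean.iloc[idx])
    extra = []
    w, h = scenario.extent
    for _ in range(counts["uncertain"]):
        extra.append(("bombus", rng.uniform(0, w), rng.uniform(0, h),
                      float(rng.integers(y0, y1 + 1)), rng.uniform(150, 500), True))
    for _ in range(counts["undated"]):
        extra.append(("bombus", rng.uniform(0, w), rng.uniform(0, h),
                      np.nan, rng.uniform(10, 50), True))
    for _ in range(counts["out_of_year"]):
        extra.append(("bombus", rng.uniform(0, w), rng.uniform(0, h),
                      float(rng.integers(y0 - 10, y0)), rng.uniform(10, 50), True))
    if extra:
        contaminated.append(
            pd.DataFrame(extra, columns=clean.columns)
        )
    table = pd.concat(contaminated, ignore_index=True)
    table = table.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)
    ledger.update(counts)
    ledger["n_total"] = len(table)
    return table, ledger


def generate_planner_corridors(
    landcover: RasterGrid,
    source_class: str = "grass",
    min_patch_ha: float = 0.5,
    buffer_m: float = 300.0,
):
    """Planner-style corridor polygons: qualifying source-habitat patches
    buffered and joined by buffered straight least-cost connectors.

    Patches are connected components (queen adjacency) of the source class
    with area >= min_patch_ha. Each pair of patches joined by an edge of
    the minimum spanning tree over between-patch distances contributes a
    connector polygon of width 2 x buffer_m. This is a plausible stand-in
    for an externally supplied corridor network, not a re-derivation of any
    particular planning tool.

    Returns a list of shapely polygons (possibly empty, with a warning).
    """
    code = CLASS_CODES[source_class]
    if not np.any(landcover.data == code):
        warnings.warn(f"source class {source_class!r} absent; empty corridor layer")
        return []
    mask = landcover.data == code
    labels, n_lab = ndimage.label(mask, structure=np.ones((3, 3)))
    cell_area_ha = landcover.cell_size**2 / 1e4
    X, Y = landcover.cell_centers()
    h = landcover.cell_size / 2.0
    patches = []
    for lab in range(1, n_lab + 1):
        sel = labels == lab
        if sel.sum() * cell_area_ha < min_patch_ha:
            continue
        boxes = [
            shapely.box(x - h, y - h, x + h, y + h)
            for x, y in zip(X[sel], Y[sel])
        ]
        patches.append(shapely.unary_union(boxes))
    if not patches:
        warnings.warn("no patch meets the minimum area; empty corridor layer")
        return []
    polys = [p.buffer(buffer_m) for p in patches]
    if len(patches) > 1:
        import networkx as nx

        g = nx.Graph()
        for i in range(len(patches)):
            for j in range(i + 1, len(patches)):
                g.add_edge(i, j, weight=patches[i].distance(patches[j]))
        for i, j in nx.minimum_spanning_tree(g).edges:
            line = shapely.shortest_line(patches[i], patches[j])
            if line.length > 0:
                polys.append(line.buffer(buffer_m, cap_style="flat"))
    return polys
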
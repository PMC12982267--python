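"""Penalized additive logistic habitat-suitability models.

Each species' probability of presence is modelled as

    logit p(s) = beta_0 + sum_j f_j(x_j(s)) + g(easting(s), northing(s))

where every f_j is a cubic-regression-spline smooth capped at four
effective degrees of freedom (basis rank 5, knots at quantiles) and g is a
low-rank thin-plate-style radial smooth over the coordinates absorbing
residual spatial autocorrelation. The model is fitted by penalized,
weighted iteratively-reweighted least squares on the binomial
log-likelihood, with two penalties per univariate smooth:

* a wiggliness penalty — the integrated squared second derivative of the
  spline, whose null space is the space of straight lines; and
* a shrinkage penalty on that null space (the "double penalty" device),
  so that with enough penalty a term can be removed from the model
  entirely rather than merely flattened to a line.

Smoothing strength is selected by grid search on weighted out-of-sample
deviance over an internal train/validation split — a deliberate, simple
stand-in for marginal-likelihood smoothness selection; the package's
validation surface is recovery of the generating linear predictor and
held-out discrimination, not coefficient-level agreement with any
particular mixed-model machinery. Terms whose fitted effective degrees of
freedom (trace of their block of the hat matrix) fall below 0.1 are
reported as shrunk out of the model.

Observation weights from the model frame keep total presence weight equal
to total background weight despite the 10x class imbalance.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .grid import RasterGrid
from .covariates import PredictorStack

__all__ = [
    "SmoothTerm",
    "SpatialTerm",
    "SuitabilityModel",
    "build_smooth",
    "build_spatial_term",
    "fit_model",
    "predict_map",
    "combine_maps",
]


# -- cubic regression spline basis ------------------------------------------
#
# Natural cubic spline through K knots, parameterized by its values at the
# knots (cardinal form). With F mapping knot values to second derivatives
# at the knots, the integrated squared second derivative penalty is
# D' B^{-1} D where D (K-2 x K) takes second differences scaled by the
# knot gaps and B is the tridiagonal Gram matrix of the linear
# second-derivative interpolant.


def _crs_matrices(knots: np.ndarray):
    k = len(knots)
    h = np.diff(knots)
    D = np.zeros((k - 2, k))
    B = np.zeros((k - 2, k - 2))
    for i in range(k - 2):
        D[i, i] = 1.0 / h[i]
        D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        D[i, i + 2] = 1.0 / h[i + 1]
        B[i, i] = (h[i] + h[i + 1]) / 3.0
        if i > 0:
            B[i, i - 1] = B[i - 1, i] = h[i] / 6.0
    F = np.linalg.solve(B, D)  # knot values -> second derivatives (interior)
    S = D.T @ F  # wiggliness penalty, PSD, null space = {1, x}
    return F, S


def _crs_eval(x: np.ndarray, knots: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Basis matrix: column j is the natural cubic spline that is 1 at
    knot j and 0 at the others, evaluated at x. Evaluation outside the
    knot range is linear (natural spline extrapolation)."""
    k = len(knots)
    x = np.asarray(x, float)
    xc = np.clip(x, knots[0], knots[-1])
    idx = np.clip(np.searchsorted(knots, xc, side="right") - 1, 0, k - 2)
    h = knots[idx + 1] - knots[idx]
    a = (knots[idx + 1] - xc) / h
    b = (xc - knots[idx]) / h
    X = np.zeros((x.size, k))
    rows = np.arange(x.size)
    # piecewise linear part in the knot values
    X[rows, idx] += a
    X[rows, idx + 1] += b
    # curvature part through the second derivatives (F maps values->gamma)
    c_a = ((a**3 - a) * h**2) / 6.0
    c_b = ((b**3 - b) * h**2) / 6.0
    G = np.zeros((x.size, k - 2))
    interior_a = idx - 1  # gamma index of left knot (gamma_0 = gamma at knot 1)
    sel = interior_a >= 0
    G[rows[sel], interior_a[sel]] += c_a[sel]
    interior_b = idx  # gamma index of right knot
    sel = interior_b <= k - 3
    G[rows[sel], interior_b[sel]] += c_b[sel]
    X += G @ F
    # linear extrapolation beyond the boundary knots
    out_lo = x < knots[0]
    out_hi = x > knots[-1]
    if out_lo.any() or out_hi.any():
        eps = 1e-6 * (knots[-1] - knots[0])
        for mask, x0 in ((out_lo, knots[0]), (out_hi, knots[-1])):
            if not mask.any():
                continue
            b0 = _crs_eval(np.array([x0]), knots, F)[0]
            b1 = (_crs_eval(np.array([x0 + (eps if x0 == knots[0] else -eps)]), knots, F)[0] - b0) / (
                eps if x0 == knots[0] else -eps
            )
            X[mask] = b0[None, :] + (x[mask, None] - x0) * b1[None, :]
    return X


@dataclass
class SmoothTerm:
    """One univariate spline smooth: basis, penalties, and the column-mean
    centring that makes it identifiable next to the intercept."""

    name: str
    knots: np.ndarray
    F: np.ndarray
    S: np.ndarray  # wiggliness penalty (rank k-2)
    U: np.ndarray  # null-space shrinkage penalty (rank 2)
    col_means: np.ndarray | None = None

    @property
    def rank(self) -> int:
        return len(self.knots)

    def design(self, x: np.ndarray, center: bool = True) -> np.ndarray:
        X = _crs_eval(np.asarray(x, float), self.knots, self.F)
        if center:
            if self.col_means is None:
                self.col_means = X.mean(axis=0)
            X = X - self.col_means
        return X


def build_smooth(values: np.ndarray, name: str = "s", df_max: int = 4) -> SmoothTerm:
    """Construct a cubic regression spline smooth of rank df_max+1 with
    knots at quantiles of the observed values, a second-derivative
    wiggliness penalty, and an identity shrinkage penalty on the penalty's
    null space (constant + linear functions)."""
    values = np.asarray(values, float)
    values = values[np.isfinite(values)]
    uniq = np.unique(values)
    if uniq.size < 10:
        raise ValueError(f"predictor {name!r} has fewer than 10 distinct values")
    k = df_max + 1
    qs = np.linspace(0, 1, k)
    knots = np.quantile(uniq, qs)
    knots = np.unique(knots)
    if len(knots) < k:  # heavy ties: spread knots over the range
        knots = np.linspace(uniq.min(), uniq.max(), k)
    F, S = _crs_matrices(knots)
    # null space of S: constant and linear in the knot values
    null = np.column_stack([np.ones(k), (knots - knots.mean()) / knots.std()])
    q, _ = np.linalg.qr(null)
    U = q @ q.T
    # scale penalties to comparable magnitude
    S = S / np.linalg.eigvalsh(S).max()
    return SmoothTerm(name=name, knots=knots, F=F, S=S, U=U)


@dataclass
class SpatialTerm:
    """Low-rank radial-basis smooth over (x, y): thin-plate kernel
    r^2 log r at space-filling centres, ridge-penalized."""

    centers: np.ndarray
    scale: float
    col_means: np.ndarray | None = None

    @property
    def rank(self) -> int:
        return len(self.centers)

    def design(self, x: np.ndarray, y: np.ndarray, center: bool = True) -> np.ndarray:
        pts = np.column_stack([np.asarray(x, float), np.asarray(y, float)])
        d = np.sqrt(
            ((pts[:, None, :] - self.centers[None, :, :]) ** 2).sum(axis=2)
        ) / self.scale
        with np.errstate(divide="ignore", invalid="ignore"):
            X = np.where(d > 0, d**2 * np.log(d), 0.0)
        if center:
            if self.col_means is None:
                self.col_means = X.mean(axis=0)
            X = X - self.col_means
        return X


def build_spatial_term(x, y, rank: int = 30, seed: int = 0) -> SpatialTerm:
    """Choose ~rank space-filling centres by k-means on the coordinates."""
    from scipy.cluster.vq import kmeans2

    pts = np.column_stack([np.asarray(x, float), np.asarray(y, float)])
    rank = min(rank, max(4, len(np.unique(pts, axis=0)) // 2))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        centers, _ = kmeans2(pts, rank, minit="++", seed=seed)
    centers = np.unique(centers, axis=0)
    span = max(np.ptp(pts[:, 0]), np.ptp(pts[:, 1]))
    return SpatialTerm(centers=centers, scale=max(span, 1e-9))


@dataclass
class SuitabilityModel:
    """A fitted per-species suitability model."""

    species: str
    terms: list[SmoothTerm]
    spatial: SpatialTerm | None
    coef: np.ndarray = field(default=None)
    lambdas: dict = field(default_factory=dict)
    edf: dict = field(default_factory=dict)
    shrunk_out: list[str] = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0
    deviance: float = np.nan
    standardisation: dict = field(default_factory=dict)

    # column layout: [intercept | term blocks... | spatial block]
    def design(self, data: dict[str, np.ndarray], x=None, y=None) -> np.ndarray:
        n = len(next(iter(data.values()))) if data else len(np.atleast_1d(x))
        cols = [np.ones((n, 1))]
        for t in self.terms:
            if t.name not in data:
                raise KeyError(f"missing predictor layer {t.name!r}")
            cols.append(t.design(data[t.name]))
        if self.spatial is not None:
            if x is None or y is None:
                raise ValueError("model has a spatial term; coordinates required")
            cols.append(self.spatial.design(x, y))
        return np.hstack(cols)

    def _blocks(self):
        """(name, start, stop) column ranges per term."""
        out = []
        start = 1
        for t in self.terms:
            out.append((t.name, start, start + t.rank))
            start += t.rank
        if self.spatial is not None:
            out.append(("spatial", start, start + self.spatial.rank))
            start += self.spatial.rank
        return out

    def linear_predictor(self, data, x=None, y=None) -> np.ndarray:
        return self.design(data, x, y) @ self.coef

    def predict(self, data, x=None, y=None) -> np.ndarray:
        return _sigmoid(self.linear_predictor(data, x, y))

    # -- serialisation -----------------------------------------------------
    def to_json(self) -> str:
        d = {
            "species": self.species,
            "coef": self.coef.tolist(),
            "lambdas": self.lambdas,
            "edf": self.edf,
            "shrunk_out": self.shrunk_out,
            "converged": self.converged,
            "deviance": self.deviance,
            "standardisation": self.standardisation,
            "terms": [
                {
                    "name": t.name,
                    "knots": t.knots.tolist(),
                    "col_means": t.col_means.tolist(),
                }
                for t in self.terms
            ],
            "spatial": None
            if self.spatial is None
            else {
                "centers": self.spatial.centers.tolist(),
                "scale": self.spatial.scale,
                "col_means": self.spatial.col_means.tolist(),
            },
        }
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SuitabilityModel":
        d = json.loads(text)
        terms = []
        for td in d["terms"]:
            knots = np.asarray(td["knots"])
            F, S = _crs_matrices(knots)
            null = np.column_stack([np.ones(len(knots)), (knots - knots.mean()) / knots.std()])
            q, _ = np.linalg.qr(null)
            t = SmoothTerm(td["name"], knots, F, S / np.linalg.eigvalsh(S).max(), q @ q.T)
            t.col_means = np.asarray(td["col_means"])
            terms.append(t)
        spatial = None
        if d["spatial"] is not None:
            spatial = SpatialTerm(np.asarray(d["spatial"]["centers"]), d["spatial"]["scale"])
            spatial.col_means = np.asarray(d["spatial"]["col_means"])
        m = cls(species=d["species"], terms=terms, spatial=spatial)
        m.coef = np.asarray(d["coef"])
        m.lambdas = d["lambdas"]
        m.edf = d["edf"]
        m.shrunk_out = d["shrunk_out"]
        m.converged = d["converged"]
        m.deviance = d["deviance"]
        m.standardisation = d["standardisation"]
        return m


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta, dtype=float)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _binomial_deviance(y, mu, w) -> float:
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0) + np.where(
            y < 1, (1 - y) * np.log((1 - y) / (1 - mu)), 0.0
        )
    return float(2.0 * np.sum(w * term))


def _penalty_matrix(model: SuitabilityModel, lam: dict) -> np.ndarray:
    p = 1 + sum(t.rank for t in model.terms) + (model.spatial.rank if model.spatial else 0)
    P = np.zeros((p, p))
    for (name, a, b), t in zip(model._blocks(), model.terms + ([None] if model.spatial else [])):
        if name == "spatial":
            P[a:b, a:b] += lam["spatial"] * np.eye(b - a)
        else:
            P[a:b, a:b] += lam[name] * t.S + lam[name + "*"] * t.U
    return P


def _pirls(X, y, w, P, max_iter=100, tol=1e-8, coef0=None):
    """Penalized IRLS for the weighted binomial log-likelihood, with
    step-halving so the penalized deviance never increases."""
    n, p = X.shape
    coef = np.zeros(p) if coef0 is None else coef0.copy()
    eta = X @ coef
    mu = _sigmoid(eta)

    def objective(c, mu):
        return _binomial_deviance(y, mu, w) + float(c @ P @ c)

    obj = objective(coef, mu)
    for it in range(1, max_iter + 1):
        W = w * mu * (1 - mu)
        W = np.maximum(W, 1e-10)
        z = eta + (y - mu) / np.maximum(mu * (1 - mu), 1e-10)
        XtW = X.T * W
        A = XtW @ X + 2.0 * P  # deviance scale: penalty gradient is 2 P c
        b = XtW @ z
        try:
            new = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            new = np.linalg.lstsq(A, b, rcond=None)[0]
        step = new - coef
        t = 1.0
        for _ in range(30):
            cand = coef + t * step
            mu_c = _sigmoid(X @ cand)
            obj_c = objective(cand, mu_c)
            if obj_c <= obj + 1e-12:
                break
            t /= 2.0
        else:
            return coef, mu, obj, it, True  # cannot improve further
        delta = abs(obj - obj_c)
        coef, mu, obj = cand, mu_c, obj_c
        eta = X @ coef
        if delta < tol * (abs(obj) + 1.0):
            return coef, mu, obj, it, True
    return coef, mu, obj, max_iter, False


def fit_model(
    frame,
    predictors: list[str],
    species: str = "species",
    df_max: int = 4,
    spatial_rank: int = 30,
    lambda_grid: np.ndarray | None = None,
    shrink_threshold: float = 0.1,
    seed: int = 0,
    use_spatial: bool = True,
    standardisation: dict | None = None,
) -> SuitabilityModel:
    """Fit the penalized additive logistic model to a model frame.

    The frame needs columns ``response``, ``weight``, ``x``, ``y`` and one
    column per predictor. ``lambda_grid`` is the grid of global smoothing
    multipliers searched by held-out weighted deviance on an internal
    75/25 split; per-term penalties share the selected multiplier (each
    term's wiggliness and shrinkage penalty carry it equally), which keeps
    selection cheap while still allowing terms to be shrunk out entirely.
    """
    rng = np.random.default_rng(seed)
    y = frame["response"].to_numpy(float)
    w = frame["weight"].to_numpy(float) if "weight" in frame else np.ones(len(frame))
    xs = frame["x"].to_numpy(float)
    ys = frame["y"].to_numpy(float)
    if lambda_grid is None:
        lambda_grid = np.logspace(-2, 5, 8)

    terms = [build_smooth(frame[p].to_numpy(float), name=p, df_max=df_max) for p in predictors]
    spatial = build_spatial_term(xs, ys, rank=spatial_rank, seed=int(rng.integers(2**31))) if use_spatial else None
    model = SuitabilityModel(species=species, terms=terms, spatial=spatial,
                             standardisation=standardisation or {})

    data = {p: frame[p].to_numpy(float) for p in predictors}
    X = model.design(data, xs, ys)

    # internal folds for smoothing selection
    n = len(y)
    n_inner = 3
    inner = rng.permutation(n) % n_inner
    splits = []
    for f in range(n_inner):
        tr, va = np.flatnonzero(inner != f), np.flatnonzero(inner == f)
        if len(np.unique(y[va])) < 2 or len(np.unique(y[tr])) < 2:
            tr = va = np.arange(n)
        splits.append((tr, va))

    def lam_dict(mult):
        lam = {}
        for t in terms:
            lam[t.name] = mult
            lam[t.name + "*"] = mult
        if spatial is not None:
            lam["spatial"] = mult * 1e-2  # spatial ridge on a gentler scale
        return lam

    # cross-validated deviance per multiplier, then a one-standard-error
    # rule: prefer the strongest smoothing whose held-out deviance is
    # within one SE of the minimum (parsimony under a flat profile)
    devs = np.zeros(len(lambda_grid))
    var_sum = np.zeros(len(lambda_grid))
    n_va_tot = 0
    for tr, va in splits:
        coef0 = None
        n_va_tot += va.size
        for k, m_ in enumerate(lambda_grid):
            P = _penalty_matrix(model, lam_dict(m_))
            coef, mu, _, _, _ = _pirls(X[tr], y[tr], w[tr], P, coef0=coef0)
            coef0 = coef
            mu_va = np.clip(_sigmoid(X[va] @ coef), 1e-12, 1 - 1e-12)
            with np.errstate(divide="ignore", invalid="ignore"):
                d_i = 2.0 * w[va] * (
                    np.where(y[va] > 0, y[va] * np.log(y[va] / mu_va), 0.0)
                    + np.where(y[va] < 1, (1 - y[va]) * np.log((1 - y[va]) / (1 - mu_va)), 0.0)
                )
            devs[k] += d_i.sum()
            var_sum[k] += d_i.size * d_i.var()
    i_min = int(np.argmin(devs))
    allowed = devs <= devs[i_min] + np.sqrt(var_sum[i_min])
    mult = float(lambda_grid[np.flatnonzero(allowed).max()])

    lam = lam_dict(mult)
    P = _penalty_matrix(model, lam)
    coef, mu, obj, n_iter, converged = _pirls(X, y, w, P)
    if not converged:
        raise RuntimeError(
            f"IRLS did not converge for {species!r} (deviance {obj:.3g} after {n_iter} iterations)"
        )
    if np.max(np.abs(coef)) > 1e4:
        raise RuntimeError(f"fit for {species!r} suggests complete separation")

    model.coef = coef
    model.lambdas = {k: float(v) for k, v in lam.items()}
    model.converged = converged
    model.n_iter = n_iter
    model.deviance = _binomial_deviance(y, mu, w)

    # effective df per term: trace of the hat-matrix block
    W = np.maximum(w * mu * (1 - mu), 1e-10)
    XtWX = (X.T * W) @ X
    Hinv = np.linalg.pinv(XtWX + 2.0 * P)
    M = Hinv @ XtWX
    for name, a, b in model._blocks():
        model.edf[name] = float(np.trace(M[a:b, a:b]))
        if name != "spatial" and model.edf[name] < shrink_threshold:
            model.shrunk_out.append(name)
    return model


def predict_map(model: SuitabilityModel, stack: PredictorStack) -> RasterGrid:
    """Evaluate the fitted model over the whole analysis grid.

    Standardisation constants stored on the model (from the fitted stack)
    are applied to raw layers when the stack provides none of its own.
    """
    grid = stack.grid
    X, Y = grid.cell_centers()
    data = {}
    for t in model.terms:
        if t.name not in stack.layers:
            raise KeyError(f"missing predictor layer {t.name!r}")
        vals = stack.layers[t.name].data
        if t.name in model.standardisation and t.name not in stack.constants:
            mu, sd = model.standardisation[t.name]
            vals = (vals - mu) / sd
        data[t.name] = vals.ravel()
    eta = model.linear_predictor(data, X.ravel(), Y.ravel())
    out = _sigmoid(eta).reshape(grid.shape)
    valid = np.ones(grid.shape, bool)
    for t in model.terms:
        valid &= stack.layers[t.name].valid
    out = np.where(valid, out, np.nan)
    return grid.like(out)


def combine_maps(maps: dict[str, RasterGrid]):
    """Sum the per-species suitability maps and min-max rescale to [0,1].

    Returns (combined map, {species: Pearson r of the combined map with
    that species' map}). Adding a constant to any one input leaves the
    combined map unchanged (min-max invariance).
    """
    if len(maps) < 2:
        raise ValueError("need at least 2 maps to combine")
    grids = list(maps.values())
    ref = grids[0]
    for g in grids[1:]:
        if not ref.aligned_with(g):
            raise ValueError("maps are not aligned")
    total = np.sum([g.data for g in grids], axis=0)
    valid = np.all([g.valid for g in grids], axis=0)
    vals = total[valid]
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        combined = np.where(valid, 0.0, np.nan)
    else:
        combined = np.where(valid, (total - lo) / (hi - lo), np.nan)
    out = ref.like(combined)
    corr = {}
    for name, g in maps.items():
        a = out.data[valid]
        b = g.data[valid]
        corr[name] = float(np.corrcoef(a, b)[0, 1]) if a.std() > 0 and b.std() > 0 else np.nan
    return out, corr
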
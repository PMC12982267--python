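"""Occurrence-record filtering, KDE-weighted background sampling, and
model-frame assembly.

Biological records, largely citizen-science, arrive with positional
uncertainty, missing dates and duplicate submissions. Records are kept
when they fall in the study year range, carry a coordinate uncertainty no
larger than the analysis resolution (100 m; missing uncertainty fails the
rule), have a known year, and are unique on (species, x, y, year).
Removals are audited per reason, applied in the fixed order
year -> uncertainty -> undated -> duplicate, so each dropped record is
counted exactly once.

Background (pseudo-absence) points are drawn per species at ten times the
presence count, weighted by a Gaussian kernel density of that species'
presences — placing background where observers plausibly were, which
offsets accessibility bias in the presences themselves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import RasterGrid
from .covariates import PredictorStack

__all__ = ["FilterAudit", "filter_records", "kde_background", "assemble_model_frame"]

REQUIRED_COLUMNS = ("species", "x", "y", "year", "uncertainty_m")


@dataclass
class FilterAudit:
    """Per-reason removal counts for one filtering pass."""

    n_input: int = 0
    n_removed_year: int = 0
    n_removed_uncertainty: int = 0
    n_removed_undated: int = 0
    n_removed_duplicate: int = 0
    n_output: int = 0

    def __post_init__(self) -> None:
        removed = (
            self.n_removed_year
            + self.n_removed_uncertainty
            + self.n_removed_undated
            + self.n_removed_duplicate
        )
        if self.n_output != self.n_input - removed:
            raise ValueError("audit counts do not balance")

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def filter_records(
    table: pd.DataFrame,
    year_min: int = 2015,
    year_max: int = 2022,
    max_uncertainty_m: float = 100.0,
) -> tuple[pd.DataFrame, FilterAudit]:
    """Apply the record-quality rules and return (kept records, audit).

    Undated records are never counted under the year rule (a missing year
    cannot fail a range test); they are removed, and counted, at the
    undated step. Records with missing uncertainty fail the uncertainty
    rule (conservative). Duplicates are identical (species, x, y, year)
    rows; the first is kept. Filtering is idempotent.
    """
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"missing required column {col!r}")
    n_input = len(table)
    if n_input == 0:
        warnings.warn("empty record table")
        return table.copy(), FilterAudit()

    t = table.copy()
    year = pd.to_numeric(t["year"], errors="coerce")
    dated = year.notna()
    in_years = dated & (year >= year_min) & (year <= year_max)
    # order: year -> uncertainty -> undated -> duplicate
    bad_year = dated & ~in_years
    t = t[~bad_year]
    n_year = int(bad_year.sum())

    unc = pd.to_numeric(t["uncertainty_m"], errors="coerce")
    ok_unc = unc.notna() & (unc <= max_uncertainty_m)
    n_unc = int((~ok_unc).sum())
    t = t[ok_unc]

    undated = pd.to_numeric(t["year"], errors="coerce").isna()
    n_undated = int(undated.sum())
    t = t[~undated]

    before = len(t)
    t = t.drop_duplicates(subset=["species", "x", "y", "year"], keep="first")
    n_dup = before - len(t)

    audit = FilterAudit(
        n_input=n_input,
        n_removed_year=n_year,
        n_removed_uncertainty=n_unc,
        n_removed_undated=n_undated,
        n_removed_duplicate=n_dup,
        n_output=len(t),
    )
    return t.reset_index(drop=True), audit


def _silverman_bandwidth(x: np.ndarray, y: np.ndarray) -> float:
    n = x.size
    sigma = np.sqrt(0.5 * (np.var(x, ddof=1) + np.var(y, ddof=1)))
    if sigma == 0:
        sigma = 1.0
    return float(sigma * n ** (-1.0 / 6.0))


def kde_background(
    presences: pd.DataFrame,
    grid: RasterGrid,
    multiplier: int = 10,
    bandwidth_m: float | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Sample background points weighted by the presence kernel density.

    For each species independently, exactly ``multiplier x n_presence``
    valid cells are sampled with probability proportional to an isotropic
    Gaussian KDE of that species' presences evaluated at cell centres
    (bandwidth: Silverman's rule on the presence coordinates unless
    given). Sampling is without replacement when enough cells exist,
    otherwise with replacement (flagged in the ``with_replacement``
    column). Points are placed at cell centres.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    valid = grid.valid
    if not valid.any():
        raise ValueError("grid has no valid cells to sample background from")
    X, Y = grid.cell_centers()
    cx, cy = X[valid], Y[valid]

    out = []
    for sp, sub in presences.groupby("species", sort=True):
        px = sub["x"].to_numpy(float)
        py = sub["y"].to_numpy(float)
        if px.size < 2:
            raise ValueError(f"species {sp!r} has fewer than 2 presences")
        h = bandwidth_m if bandwidth_m is not None else _silverman_bandwidth(px, py)
        # Gaussian KDE at cell centres, chunked over presences
        dens = np.zeros(cx.size)
        for i in range(0, px.size, 256):
            dx = cx[:, None] - px[None, i : i + 256]
            dy = cy[:, None] - py[None, i : i + 256]
            dens += np.exp(-(dx**2 + dy**2) / (2 * h**2)).sum(axis=1)
        if dens.sum() == 0:
            dens[:] = 1.0
        p = dens / dens.sum()
        n_bg = multiplier * px.size
        replace = n_bg > np.count_nonzero(p)
        if replace:
            warnings.warn(f"sampling background with replacement for {sp!r}")
        idx = rng.choice(cx.size, size=n_bg, replace=replace, p=p)
        out.append(
            pd.DataFrame(
                {
                    "species": sp,
                    "x": cx[idx],
                    "y": cy[idx],
                    "year": np.nan,
                    "uncertainty_m": 0.0,
                    "is_presence": False,
                    "with_replacement": replace,
                }
            )
        )
    bg = pd.concat(out, ignore_index=True)
    bg["provenance"] = "background"
    return bg


def assemble_model_frame(
    presences: pd.DataFrame,
    background: pd.DataFrame,
    stack: PredictorStack,
) -> pd.DataFrame:
    """Join presences and background into one fitting frame.

    The response is 1/0; observation weights balance the classes: each
    presence carries weight n_background/n_presence, each background point
    weight 1, then all weights are rescaled to mean 1. Predictor values
    are read from the analysis cell containing each point; points outside
    the stack extent are dropped with a warning.
    """
    pres = presences.copy()
    pres["response"] = 1.0
    bg = background.copy()
    bg["response"] = 0.0
    frame = pd.concat([pres, bg], ignore_index=True)

    vals = stack.values_at(frame["x"].to_numpy(float), frame["y"].to_numpy(float))
    inside = np.ones(len(frame), bool)
    for name, v in vals.items():
        frame[name] = v
        inside &= np.isfinite(v)
    n_dropped = int((~inside).sum())
    if n_dropped:
        warnings.warn(f"{n_dropped} points outside the predictor extent dropped")
    frame = frame[inside].reset_index(drop=True)

    n_pres = int((frame["response"] == 1).sum())
    n_bg = int((frame["response"] == 0).sum())
    if n_pres == 0 or n_bg == 0:
        raise ValueError("frame needs both presences and background")
    w = np.where(frame["response"] == 1, n_bg / n_pres, 1.0)
    frame["weight"] = w / w.mean()
    frame.attrs["n_dropped_outside"] = n_dropped
    return frame
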
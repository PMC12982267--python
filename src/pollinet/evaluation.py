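"""Model evaluation: random and spatially blocked k-fold cross-validation
with AUC, the continuous Boyce index, and TSS with threshold selection.

Random 10-fold CV measures interpolation performance; spatially blocked CV
(5 km blocks allocated whole to folds) enforces geographic separation
between training and test data, giving a more conservative estimate when
records are spatially autocorrelated. Because whole blocks move together,
spatial folds can be unbalanced — that is expected and reported, not
corrected. A repeated 75/25 split mode is also provided for designs that
hold out a single fraction repeatedly rather than partitioning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FoldAssignment",
    "MetricReport",
    "make_folds",
    "auc",
    "boyce_index",
    "tss_curve",
    "cross_validate",
]


@dataclass
class FoldAssignment:
    mode: str  # random | spatial_block | repeated_split
    k: int
    fold_id: np.ndarray  # per-record fold (repeated_split: test-set id, -1 = never)
    block_id: np.ndarray | None = None
    block_size_m: float | None = None
    seed: int | None = None

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_id == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        if self.mode == "repeated_split":
            return np.flatnonzero(self.fold_id != fold)
        return np.flatnonzero(self.fold_id != fold)


def make_folds(
    records: pd.DataFrame,
    mode: str = "random",
    k: int = 10,
    block_size_m: float = 5000.0,
    seed: int = 0,
    test_fraction: float = 0.25,
) -> FoldAssignment:
    """Assign records to folds.

    random
        Uniform assignment: a permutation split into k nearly equal folds
        (exactly equal when k divides n).
    spatial_block
        The extent is tiled into squares of ``block_size_m``; blocks are
        shuffled and dealt round-robin to folds so every record in a block
        shares a fold. Errors if there are fewer non-empty blocks than
        folds.
    repeated_split
        k independent draws of a ``test_fraction`` test set; fold_id here
        is the id of the *first* split a record tests in (metadata only —
        use :meth:`FoldAssignment.test_indices` per split).
    """
    rng = np.random.default_rng(seed)
    n = len(records)
    if mode == "random":
        if n < k:
            raise ValueError(f"need at least k={k} records")
        ids = np.repeat(np.arange(k), int(np.ceil(n / k)))[:n]
        fold = ids[rng.permutation(n)]
        return FoldAssignment("random", k, fold, seed=seed)
    if mode == "spatial_block":
        x = records["x"].to_numpy(float)
        y = records["y"].to_numpy(float)
        bx = np.floor((x - x.min()) / block_size_m).astype(int)
        by = np.floor((y - y.min()) / block_size_m).astype(int)
        block = bx * (by.max() + 1) + by
        uniq = np.unique(block)
        if uniq.size < k:
            raise ValueError(
                f"only {uniq.size} non-empty {block_size_m:.0f} m blocks for k={k} folds;"
                " use smaller blocks or fewer folds"
            )
        order = rng.permutation(uniq.size)
        block_fold = {int(b): int(i % k) for i, b in zip(np.arange(uniq.size), uniq[order])}
        fold = np.array([block_fold[int(b)] for b in block])
        return FoldAssignment("spatial_block", k, fold, block_id=block,
                              block_size_m=block_size_m, seed=seed)
    if mode == "repeated_split":
        n_test = max(1, int(round(test_fraction * n)))
        first = np.full(n, -1)
        splits = []
        for rep in range(k):
            test = rng.choice(n, n_test, replace=False)
            splits.append(test)
            newly = test[first[test] < 0]
            first[newly] = rep
        fa = FoldAssignment("repeated_split", k, first, seed=seed)
        fa._splits = splits
        return fa
    raise ValueError(f"unknown mode {mode!r}")


def auc(presence_scores, background_scores) -> float:
    """Probability that a presence outscores a background point, ties
    counted one half (the rank / Mann-Whitney formulation)."""
    p = np.asarray(presence_scores, float)
    b = np.asarray(background_scores, float)
    if p.size == 0 or b.size == 0:
        raise ValueError("both score sets must be non-empty")
    if np.isnan(p).any() or np.isnan(b).any():
        raise ValueError("NaN scores")
    ranks = stats.rankdata(np.concatenate([p, b]))
    r_p = ranks[: p.size].sum()
    return float((r_p - p.size * (p.size + 1) / 2) / (p.size * b.size))


def boyce_index(
    presence_scores,
    landscape_scores,
    n_classes: int = 101,
    window_width: float = 0.1,
) -> float:
    """Continuous Boyce index.

    Scores are min-max scaled to [0,1] by the landscape range; overlapping
    windows of ``window_width`` are centred at ``n_classes`` evenly spaced
    midpoints. Per window, P/E = (fraction of presences in the window) /
    (fraction of landscape in the window); windows with zero expected
    fraction are skipped. The index is the Spearman correlation between
    P/E and the window midpoint: +1 when suitability ranks presences
    perfectly, ~0 when no better than random.
    """
    p = np.asarray(presence_scores, float)
    l = np.asarray(landscape_scores, float)
    lo, hi = np.nanmin(l), np.nanmax(l)
    if not np.isfinite(lo) or hi == lo:
        raise ValueError("landscape scores are degenerate")
    p = (p - lo) / (hi - lo)
    l = (l - lo) / (hi - lo)
    if np.all((p < 0) | (p > 1)):
        raise ValueError("all presences fall outside the landscape score range")
    mids = np.linspace(0, 1, n_classes)
    half = window_width / 2.0
    pe, used_mids = [], []
    for m in mids:
        lo_w, hi_w = m - half, m + half
        e = np.mean((l >= lo_w) & (l <= hi_w))
        if e == 0:
            continue
        f = np.mean((p >= lo_w) & (p <= hi_w))
        pe.append(f / e)
        used_mids.append(m)
    if len(pe) < 2:
        raise ValueError("too few usable windows")
    rho = stats.spearmanr(used_mids, pe).statistic
    return float(rho)


def tss_curve(scores, labels, threshold_grid=None) -> dict:
    """Sensitivity, specificity and TSS over a threshold grid, plus the
    maxSSS (max sensitivity+specificity) and MDT (min |sens-spec|)
    thresholds, ties broken toward the smaller threshold.

    Predictions >= threshold count as positive.
    """
    s = np.asarray(scores, float)
    y = np.asarray(labels, float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if threshold_grid is None:
        threshold_grid = np.unique(np.concatenate([np.unique(s), np.linspace(0, 1, 101)]))
    grid = np.asarray(threshold_grid, float)
    npos = (y == 1).sum()
    nneg = (y == 0).sum()
    sens = np.array([np.sum((s >= t) & (y == 1)) / npos for t in grid])
    spec = np.array([np.sum((s < t) & (y == 0)) / nneg for t in grid])
    tss = sens + spec - 1.0
    ssum = sens + spec
    i_max = int(np.argmax(ssum))  # argmax returns the first (smallest) on ties
    i_mdt = int(np.argmin(np.abs(sens - spec)))
    return {
        "threshold": grid,
        "sensitivity": sens,
        "specificity": spec,
        "tss": tss,
        "max_sss_threshold": float(grid[i_max]),
        "max_tss": float(tss[i_max]),
        "mdt_threshold": float(grid[i_mdt]),
    }


@dataclass
class MetricReport:
    mode: str
    per_fold: pd.DataFrame
    seed: int | None = None
    skipped_folds: list[int] = field(default_factory=list)

    @property
    def summary(self) -> dict:
        out = {}
        for m in ("auc", "boyce", "tss", "threshold"):
            vals = self.per_fold[m].to_numpy(float)
            vals = vals[np.isfinite(vals)]
            out[m] = (float(np.mean(vals)), float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0)
        return out


def cross_validate(frame, folds: FoldAssignment, fit, score) -> MetricReport:
    """Refit per fold and evaluate on the held-out records.

    ``fit(train_frame) -> model`` and ``score(model, test_frame) ->
    array`` abstract the model so the same harness serves the suitability
    model and any oracle. Per fold: AUC of presence vs background scores,
    continuous Boyce (presence scores against all test scores as the
    landscape), and TSS at the maxSSS threshold. Folds whose test set has
    a single class are skipped with a warning.
    """
    rows, skipped = [], []
    for f in range(folds.k):
        if folds.mode == "repeated_split":
            test_idx = folds._splits[f]
            train_idx = np.setdiff1d(np.arange(len(frame)), test_idx)
        else:
            test_idx = folds.test_indices(f)
            train_idx = folds.train_indices(f)
        test = frame.iloc[test_idx]
        train = frame.iloc[train_idx]
        if test.empty or len(np.unique(test["response"])) < 2 or len(np.unique(train["response"])) < 2:
            warnings.warn(f"fold {f} skipped: single-class train or test set")
            skipped.append(f)
            continue
        model = fit(train)
        s = np.asarray(score(model, test), float)
        y = test["response"].to_numpy(float)
        fold_auc = auc(s[y == 1], s[y == 0])
        try:
            fold_boyce = boyce_index(s[y == 1], s)
        except ValueError:
            fold_boyce = np.nan
        curve = tss_curve(s, y)
        rows.append(
            {
                "fold": f,
                "n_test": len(test),
                "auc": fold_auc,
                "boyce": fold_boyce,
                "tss": curve["max_tss"],
                "threshold": curve["max_sss_threshold"],
            }
        )
    if not rows:
        raise ValueError("no usable folds")
    return MetricReport(folds.mode, pd.DataFrame(rows), seed=folds.seed, skipped_folds=skipped)
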
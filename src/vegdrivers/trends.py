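"""Per-series linear trend estimation and trend-class area summaries.

A vegetation (or climate) time series is reduced to a least-squares slope
with a two-sided t-test on the slope, then classified into significant /
non-significant increase or decrease at a chosen level alpha.  Raster
stacks are handled with the same estimator vectorised over cells, and
classified grids are summarised as area fractions — the standard
"x% of the basin shows an increasing trend" product.

The slope estimator is ordinary least squares,
``slope = sum((t - t̄)(y - ȳ)) / sum((t - t̄)^2)``, with the p-value from a
t-test on n − 2 degrees of freedom.  A Theil–Sen / Mann–Kendall variant is
available via ``method="theilsen"`` for robustness checks; OLS is the
default.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import stats

__all__ = [
    "TrendResult",
    "TrendClass",
    "TrendFitError",
    "fit_linear_trend",
    "classify_trend",
    "segment_rates",
    "raster_trends",
    "classify_raster",
    "area_fractions",
]


class TrendFitError(ValueError):
    """Raised when a series cannot support a trend fit."""


@dataclass(frozen=True)
class TrendResult:
    """Fitted linear trend: slope in units/year, two-sided p-value, n points."""

    slope: float
    intercept: float
    p_value: float
    n: int


class TrendClass(Enum):
    SIG_INC = "sig_inc"
    NONSIG_INC = "nonsig_inc"
    NONSIG_DEC = "nonsig_dec"
    SIG_DEC = "sig_dec"
    FLAT = "flat"
    NO_DATA = "no_data"


def _clean(times, values):
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape:
        raise TrendFitError("times and values must have the same length")
    if t.size >= 2 and np.any(np.diff(t) <= 0):
        raise TrendFitError("times must be strictly increasing")
    ok = np.isfinite(t) & np.isfinite(y)
    return t[ok], y[ok]


def fit_linear_trend(times, values, method: str = "ols") -> TrendResult:
    """Fit a linear trend to one series.

    Parameters
    ----------
    times : array-like of int
        Calendar years, strictly increasing.
    values : array-like of float
        Response in native units; NaNs are dropped pairwise.
    method : {"ols", "theilsen"}
        "ols" gives the closed-form least-squares slope with a two-sided
        t-test; "theilsen" gives the median-of-pairwise-slopes estimator
        with a Mann–Kendall p-value.
    """
    t, y = _clean(times, values)
    if t.size < 3:
        raise TrendFitError(f"need >=3 finite points, got {t.size}")
    if np.ptp(t) == 0:
        raise TrendFitError("zero time variance")
    if method == "ols":
        tc = t - t.mean()
        yc = y - y.mean()
        sxx = float(tc @ tc)
        slope = float(tc @ yc) / sxx
        intercept = float(y.mean() - slope * t.mean())
        resid = yc - slope * tc
        dof = t.size - 2
        rss = float(resid @ resid)
        if rss <= 0.0:
            p = 0.0 if slope != 0.0 else 1.0
        else:
            se = np.sqrt(rss / dof / sxx)
            p = float(2.0 * stats.t.sf(abs(slope) / se, dof))
        return TrendResult(slope, intercept, p, int(t.size))
    if method == "theilsen":
        slope, intercept, _, _ = stats.theilslopes(y, t)
        p = float(stats.kendalltau(t, y).pvalue)
        if np.isnan(p):  # constant series
            p = 1.0
        return TrendResult(float(slope), float(intercept), p, int(t.size))
    raise ValueError(f"unknown method {method!r}")


def classify_trend(result: TrendResult, alpha: float = 0.05) -> TrendClass:
    """Classify a fitted trend at significance level ``alpha``.

    SIG_INC iff slope > 0 and p < alpha; NONSIG_INC iff slope > 0 and
    p >= alpha; mirrored for decreases; FLAT iff slope is exactly zero.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if result.slope == 0.0:
        return TrendClass.FLAT
    if result.slope > 0.0:
        return TrendClass.SIG_INC if result.p_value < alpha else TrendClass.NONSIG_INC
    return TrendClass.SIG_DEC if result.p_value < alpha else TrendClass.NONSIG_DEC


def segment_rates(times, values, split_year: int, method: str = "ols"):
    """Independent trend fits before and after a policy breakpoint year.

    The split year belongs to BOTH segments (a 1980–2000 / 2000–2019
    convention).  Returns ``(pre, post)`` TrendResults.
    """
    t = np.asarray(times)
    y = np.asarray(values)
    pre = t <= split_year
    post = t >= split_year
    if pre.sum() < 3:
        raise TrendFitError(f"pre-{split_year} segment has {int(pre.sum())} points; need >=3")
    if post.sum() < 3:
        raise TrendFitError(f"post-{split_year} segment has {int(post.sum())} points; need >=3")
    return fit_linear_trend(t[pre], y[pre], method), fit_linear_trend(t[post], y[post], method)


def raster_trends(stack: np.ndarray, years) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised OLS trend over a (n_years, rows, cols) stack.

    NaN cells are dropped per-cell (pairwise); cells with fewer than 3
    remaining points get NaN slope/p and n < 3.

    Returns (slope, p_value, n_valid) grids.
    """
    stack = np.asarray(stack, dtype=float)
    t = np.asarray(years, dtype=float)
    if stack.shape[0] != t.size:
        raise ValueError(f"stack has {stack.shape[0]} bands but {t.size} years given")
    valid = np.isfinite(stack)
    n = valid.sum(axis=0)
    tt = t[:, None, None]
    y = np.where(valid, stack, 0.0)
    tv = np.where(valid, tt, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tbar = tv.sum(axis=0) / n
        ybar = y.sum(axis=0) / n
        tc = np.where(valid, tt - tbar, 0.0)
        yc = np.where(valid, stack - ybar, 0.0)
        sxx = (tc * tc).sum(axis=0)
        sxy = (tc * yc).sum(axis=0)
        slope = sxy / sxx
        rss = (yc * yc).sum(axis=0) - slope * sxy
        dof = n - 2
        var = rss / np.where(dof > 0, dof, 1) / sxx
        se = np.sqrt(np.clip(var, 0.0, None))
        tstat = np.abs(slope) / se
    p = 2.0 * stats.t.sf(tstat, np.where(dof > 0, dof, 1))
    # exact fits: zero residual variance
    p = np.where((rss <= 1e-300) & (slope != 0), 0.0, p)
    p = np.where(slope == 0, 1.0, p)
    bad = (n < 3) | (sxx <= 0)
    slope = np.where(bad, np.nan, slope)
    p = np.where(bad, np.nan, p)
    return slope, p, n


def classify_raster(slope: np.ndarray, p: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Cell-wise trend classification; NaN slope cells become NO_DATA."""
    out = np.full(slope.shape, TrendClass.NO_DATA, dtype=object)
    ok = np.isfinite(slope) & np.isfinite(p)
    out[ok & (slope > 0) & (p < alpha)] = TrendClass.SIG_INC
    out[ok & (slope > 0) & (p >= alpha)] = TrendClass.NONSIG_INC
    out[ok & (slope < 0) & (p >= alpha)] = TrendClass.NONSIG_DEC
    out[ok & (slope < 0) & (p < alpha)] = TrendClass.SIG_DEC
    out[ok & (slope == 0)] = TrendClass.FLAT
    return out


def area_fractions(class_grid: np.ndarray, mask: np.ndarray | None = None,
                   merge_flat: bool = False) -> dict[TrendClass, float]:
    """Fraction of (masked, non-NO_DATA) cells in each trend class.

    ``mask`` selects the valid analysis area.  NO_DATA cells are excluded
    from the denominator.  With ``merge_flat`` exactly-zero-slope cells are
    folded into NONSIG_INC for summary purposes.
    """
    grid = np.asarray(class_grid, dtype=object)
    if mask is None:
        mask = np.ones(grid.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid.shape:
        raise ValueError("mask shape does not match class grid")
    sel = grid[mask]
    sel = sel[sel != TrendClass.NO_DATA]
    if sel.size == 0:
        raise ValueError("empty mask: no valid cells to summarise")
    out: dict[TrendClass, float] = {}
    for cls in TrendClass:
        if cls is TrendClass.NO_DATA:
            continue
        out[cls] = float(np.mean(sel == cls))
    if merge_flat:
        out[TrendClass.NONSIG_INC] += out.pop(TrendClass.FLAT)
    return out
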
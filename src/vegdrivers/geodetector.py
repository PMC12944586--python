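"""Geographical-detector factor analysis: the q-statistic.

The factor detector asks how much of the spatial variance of a response
(here the leaf area index across administrative units) is explained by a
stratification of a candidate driver:

    q = 1 - SSW / SST,   SSW = sum_h N_h * sigma_h^2,   SST = N * sigma^2,

with POPULATION variances throughout so the decomposition
SSW + sum_h N_h (mean_h - mean)^2 = SST holds exactly and q is in [0, 1].
q = 0 means the stratification carries no information about the response;
q = 1 means the response is constant within every stratum.

Continuous drivers are discretised (default: quantile breaks, L = 5);
significance comes from a seeded permutation test (default) or the
noncentral-F reference distribution used by the canonical geodetector
software.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Stratification",
    "QResult",
    "discretize",
    "q_statistic",
    "q_significance",
    "factor_detector_table",
    "stars",
]


@dataclass(frozen=True)
class Stratification:
    """Integer stratum labels in 1..L for each unit."""

    labels: np.ndarray
    L: int
    method: str = "given"

    def __post_init__(self):
        lab = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "labels", lab)
        if lab.size == 0:
            raise ValueError("empty stratification")
        if lab.min() < 1 or lab.max() > self.L:
            raise ValueError("labels must lie in 1..L")


@dataclass
class QResult:
    """q with its variance decomposition and (optional) significance."""

    q: float
    N: int
    n_h: dict[int, int]
    sigma2_h: dict[int, float]
    sigma2: float
    ssw: float
    sst: float
    p_value: float | None = None
    method: str = ""
    extras: dict = field(default_factory=dict)


def _jenks_breaks_1d(values: np.ndarray, L: int) -> np.ndarray:
    """Exact natural-breaks (minimum within-class SSD) labels by DP."""
    order = np.argsort(values, kind="stable")
    x = values[order]
    n = x.size
    cs = np.concatenate([[0.0], np.cumsum(x)])
    cs2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def ssd(i, j):  # within-class sum of squared deviations of x[i:j]
        m = j - i
        s = cs[j] - cs[i]
        return (cs2[j] - cs2[i]) - s * s / m

    INF = np.inf
    cost = np.full((L + 1, n + 1), INF)
    back = np.zeros((L + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for k in range(1, L + 1):
        for j in range(k, n + 1):
            best, arg = INF, k - 1
            for i in range(k - 1, j):
                c = cost[k - 1, i] + ssd(i, j)
                if c < best:
                    best, arg = c, i
            cost[k, j] = best
            back[k, j] = arg
    labels_sorted = np.empty(n, dtype=int)
    j = n
    for k in range(L, 0, -1):
        i = back[k, j]
        labels_sorted[i:j] = k
        j = i
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return labels


def discretize(values, L: int, method: str = "quantile") -> Stratification:
    """Partition a continuous driver into L strata.

    quantile: breaks at k/L sample quantiles, ties assigned to the lower
    stratum; equal_interval: equal-width bins over the range; jenks:
    exact natural breaks (minimum within-class sum of squares).  Empty
    strata are collapsed and L reduced accordingly.  A constant input
    yields a single stratum (q will be 0 downstream).
    """
    x = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("driver values must be finite")
    if L < 2:
        raise ValueError("L must be >= 2")
    if np.ptp(x) == 0:
        return Stratification(np.ones(x.size, dtype=int), 1, method)
    if method == "quantile":
        edges = np.quantile(x, np.arange(1, L) / L)
        labels = np.searchsorted(edges, x, side="left") + 1
    elif method == "equal_interval":
        edges = np.linspace(x.min(), x.max(), L + 1)[1:-1]
        labels = np.searchsorted(edges, x, side="left") + 1
    elif method == "jenks":
        if np.unique(x).size < L:
            raise ValueError(f"need >= {L} distinct values for jenks")
        labels = _jenks_breaks_1d(x, L)
    else:
        raise ValueError(f"unknown discretization method {method!r}")
    # collapse empty strata so labels are contiguous 1..L'
    present = np.unique(labels)
    remap = {old: new for new, old in enumerate(present, start=1)}
    labels = np.array([remap[v] for v in labels], dtype=int)
    return Stratification(labels, len(present), method)


def _q_from_arrays(y: np.ndarray, labels: np.ndarray, L: int) -> tuple[float, float, float]:
    """(q, ssw, sst) using population variances; fully vectorised."""
    n = np.bincount(labels, minlength=L + 1)[1:]
    s = np.bincount(labels, weights=y, minlength=L + 1)[1:]
    s2 = np.bincount(labels, weights=y * y, minlength=L + 1)[1:]
    with np.errstate(invalid="ignore", divide="ignore"):
        ssw = float(np.sum(np.where(n > 0, s2 - s * s / np.where(n > 0, n, 1), 0.0)))
    sst = float(np.sum(y * y) - y.sum() ** 2 / y.size)
    return 1.0 - ssw / sst, ssw, sst


def q_statistic(y, strata: Stratification) -> QResult:
    """Compute q = 1 - SSW/SST for a response and a stratification."""
    y = np.asarray(y, dtype=float)
    labels = strata.labels
    if y.size != labels.size:
        raise ValueError("response and stratification lengths differ")
    if y.size < 2:
        raise ValueError("need at least 2 units")
    sigma2 = float(np.var(y))  # population variance
    if sigma2 == 0.0:
        raise ValueError("response constant; q undefined")
    q, ssw, sst = _q_from_arrays(y, labels, strata.L)
    n_h, sigma2_h = {}, {}
    for h in range(1, strata.L + 1):
        sel = y[labels == h]
        n_h[h] = int(sel.size)
        sigma2_h[h] = float(np.var(sel)) if sel.size else 0.0
    # clamp tiny negative float noise
    q = min(max(q, 0.0), 1.0)
    return QResult(q, int(y.size), n_h, sigma2_h, sigma2, ssw, sst, method=strata.method)


def q_significance(y, strata: Stratification, method: str = "permutation",
                   B: int = 999, seed: int | None = 0) -> float:
    """p-value for the q-statistic.

    permutation: relabel units at random B times (seeded) and count
    permuted q >= observed, p = (1 + #exceed) / (B + 1).  noncentral_f:
    the transformation F = ((N-L)/(L-1)) * q/(1-q) referred to its
    noncentral F law with the standard noncentrality term.
    """
    y = np.asarray(y, dtype=float)
    labels = strata.labels
    L = strata.L
    if L <= 1:
        return 1.0
    q_obs, _, _ = _q_from_arrays(y, labels, L)
    if method == "permutation":
        if B < 99:
            raise ValueError("B must be >= 99 for a stable permutation p-value")
        rng = np.random.default_rng(seed)
        n = np.bincount(labels, minlength=L + 1)[1:]
        sst = float(np.sum(y * y) - y.sum() ** 2 / y.size)
        # permuting labels == permuting y against fixed group slots
        masks = [labels == h for h in range(1, L + 1)]
        exceed = 0
        perms = rng.permuted(np.broadcast_to(y, (B, y.size)).copy(), axis=1)
        ssw_perm = np.zeros(B)
        for h, m in enumerate(masks):
            if n[h] == 0:
                continue
            block = perms[:, m]
            s = block.sum(axis=1)
            ssw_perm += (block * block).sum(axis=1) - s * s / n[h]
        q_perm = 1.0 - ssw_perm / sst
        exceed = int(np.sum(q_perm >= q_obs - 1e-12))
        return (1 + exceed) / (B + 1)
    if method == "noncentral_f":
        N = y.size
        if q_obs >= 1.0:
            return 0.0
        F = (N - L) / (L - 1) * q_obs / (1.0 - q_obs)
        means = np.array([y[labels == h].mean() for h in range(1, L + 1)])
        n = np.bincount(labels, minlength=L + 1)[1:].astype(float)
        sigma2 = float(np.var(y))
        lam = (np.sum(means**2 * n) - (np.sum(np.sqrt(n) * means)) ** 2 / N) / sigma2
        lam = max(lam, 0.0)
        return float(stats.ncf.sf(F, L - 1, N - L, lam))
    raise ValueError(f"unknown significance method {method!r}")


def stars(p: float | None) -> str:
    """Significance stars: ** p<0.01, * p<0.05, '' otherwise."""
    if p is None or np.isnan(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def factor_detector_table(panel: pd.DataFrame, response: str, factors: list[str],
                          years: list[int], L: int = 5, method: str = "quantile",
                          sig_method: str = "permutation", B: int = 999,
                          seed: int = 0) -> pd.DataFrame:
    """q and significance per (factor, year): the factor-detector matrix.

    ``panel`` is tidy with columns unit_id, year, the response and one
    column per factor.  A factor missing (all-NaN) in a year yields a
    missing cell, matching published tables that print "-" for a policy
    variable before its programme started.  Misaligned units raise.

    Returns a DataFrame indexed by factor with MultiIndex columns
    (year, {"q", "p", "stars"}).
    """
    cols: dict[tuple[int, str], dict[str, float | str | None]] = {}
    for yr in years:
        sub = panel[panel["year"] == yr]
        if sub.empty:
            raise ValueError(f"no records for year {yr}")
        if sub["unit_id"].duplicated().any():
            raise ValueError(f"duplicate unit_id records in year {yr}")
        yv = sub[response].to_numpy(dtype=float)
        if not np.all(np.isfinite(yv)):
            raise ValueError(f"response {response!r} has missing values in year {yr}")
        for fac in factors:
            xv = sub[fac].to_numpy(dtype=float)
            if np.all(np.isnan(xv)):
                cols.setdefault((yr, fac), {"q": np.nan, "p": np.nan, "stars": ""})
                continue
            if np.any(np.isnan(xv)):
                raise ValueError(f"factor {fac!r} partially missing in year {yr}")
            strat = discretize(xv, L, method)
            res = q_statistic(yv, strat)
            cell_salt = zlib.crc32(f"{fac}:{yr}".encode())  # stable across processes
            p = q_significance(yv, strat, sig_method, B=B,
                               seed=(seed * 1000003 + cell_salt) % (2**31))
            cols[(yr, fac)] = {"q": res.q, "p": p, "stars": stars(p)}
    out = pd.DataFrame(
        {(yr, stat): {fac: cols[(yr, fac)][stat] for fac in factors}
         for yr in years for stat in ("q", "p", "stars")}
    )
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["year", "stat"])
    return out.loc[factors]
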
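"""Geographically and Temporally Weighted Regression (GTWR).

The model lets every regression coefficient vary over space and time:

    y_i = beta_0(u_i, v_i, t_i) + sum_k beta_k(u_i, v_i, t_i) x_ik + eps_i

Each record gets its own weighted-least-squares fit, with weights decaying
in the combined spatiotemporal distance

    d_ij^2 = (u_i - u_j)^2 + (v_i - v_j)^2 + tau * (t_i - t_j)^2,

where ``tau`` (km^2/yr^2) converts years to kilometre-equivalents.  The
kernel bandwidth is selected by leave-one-out cross-validation (default)
or AICc over a candidate grid with golden-section refinement; ``tau`` can
itself be selected over a small outer grid on the same criterion.

The focal record is included in its own local fit (standard GWR
practice); LOOCV zeroes the self-weight only for scoring.  Near-singular
local systems are retried with a trace-scaled ridge and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "PanelDataset",
    "GTWRConfig",
    "GTWRResult",
    "st_distance",
    "st_distance_matrix",
    "kernel_weight",
    "fit_local_wls",
    "loocv_score",
    "select_bandwidth",
    "fit_gtwr",
    "coefficient_summary",
    "lonlat_to_km",
]

EARTH_RADIUS_KM = 6371.0088


@dataclass
class PanelDataset:
    """Unit-year records with planar coordinates and named predictors.

    ``frame`` columns: unit_id, x_km, y_km, year, the response column and
    one column per predictor.
    """

    frame: pd.DataFrame
    predictors: list[str]
    response: str = "response"

    def __post_init__(self):
        need = {"unit_id", "x_km", "y_km", "year", self.response, *self.predictors}
        missing = need - set(self.frame.columns)
        if missing:
            raise ValueError(f"panel missing columns: {sorted(missing)}")
        if self.frame.duplicated(["unit_id", "year"]).any():
            raise ValueError("duplicate (unit_id, year) records")

    @property
    def n(self) -> int:
        return len(self.frame)

    def points(self) -> np.ndarray:
        """(n, 3) array of (u, v, t)."""
        return self.frame[["x_km", "y_km", "year"]].to_numpy(dtype=float)

    def design(self) -> np.ndarray:
        """(n, p+1) design matrix with leading intercept column."""
        X = self.frame[self.predictors].to_numpy(dtype=float)
        return np.column_stack([np.ones(len(X)), X])

    def y(self) -> np.ndarray:
        return self.frame[self.response].to_numpy(dtype=float)


@dataclass
class GTWRConfig:
    kernel: str = "gaussian"            # or "bisquare"
    tau: float | None = None            # km^2/yr^2; None => select over tau_grid
    bandwidth: float | None = None      # spatiotemporal km; None => select
    adaptive: bool = False              # if True, bandwidth is a neighbour count
    bandwidth_grid: tuple = ()          # candidates; empty => auto from data diameter
    criterion: str = "loocv"            # or "aicc"
    # geometric grid: with coordinates in km and time in years the right
    # km^2/yr^2 equivalence can span orders of magnitude
    tau_grid: tuple = (1.0, 4.0, 16.0, 64.0, 256.0)
    min_effective_weight: float = 1e-3  # lower bound on sum of non-self weights
    ridge_eps: float = 1e-8             # trace-scaled diagonal for near-singular fits
    lonlat: bool = False                # coordinates given as lon/lat degrees

    def __post_init__(self):
        if self.kernel not in ("gaussian", "bisquare"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.tau is not None and self.tau < 0:
            raise ValueError("tau must be >= 0")
        if self.bandwidth is not None and self.bandwidth <= 0:
            raise ValueError("bandwidth must be > 0")
        if self.ridge_eps < 0:
            raise ValueError("ridge_eps must be >= 0")


@dataclass
class GTWRResult:
    """Per-record local coefficients plus global diagnostics."""

    frame: pd.DataFrame          # unit_id, year, beta_0, beta_<name>..., fitted,
    # residual, local_r2, flagged
    predictors: list[str]
    r2: float
    rmse: float
    aicc: float
    trace_S: float
    bandwidth: float
    tau: float
    config: GTWRConfig
    n_flagged: int = 0
    meta: dict = field(default_factory=dict)

    def betas(self) -> pd.DataFrame:
        cols = ["beta_0"] + [f"beta_{p}" for p in self.predictors]
        return self.frame[["unit_id", "year", *cols]]


def lonlat_to_km(lon, lat) -> tuple[np.ndarray, np.ndarray]:
    """Equirectangular projection about the domain centroid."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    lat0 = np.deg2rad(lat.mean())
    x = EARTH_RADIUS_KM * np.cos(lat0) * np.deg2rad(lon - lon.mean())
    y = EARTH_RADIUS_KM * np.deg2rad(lat - lat.mean())
    return x, y


def st_distance(a, b, tau: float) -> float:
    """Spatiotemporal distance between two (u, v, t) points."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d2 = (a[0] - b[0]) ** 2 + (a[1] - b[1]) ** 2 + tau * (a[2] - b[2]) ** 2
    return float(np.sqrt(d2))


def st_distance_matrix(pts: np.ndarray, tau: float) -> np.ndarray:
    """Dense pairwise spatiotemporal distance matrix for (n, 3) points."""
    du = pts[:, 0:1] - pts[:, 0:1].T
    dv = pts[:, 1:2] - pts[:, 1:2].T
    dt = pts[:, 2:3] - pts[:, 2:3].T
    return np.sqrt(du * du + dv * dv + tau * dt * dt)


def kernel_weight(d, bandwidth: float, kernel: str = "gaussian") -> np.ndarray:
    """Kernel weight(s) for distance(s) d at the given bandwidth.

    gaussian: exp(-d^2/b^2); bisquare: (1-(d/b)^2)^2 for d < b, else 0.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    d = np.asarray(d, dtype=float)
    if kernel == "gaussian":
        return np.exp(-((d / bandwidth) ** 2))
    if kernel == "bisquare":
        r = d / bandwidth
        w = (1.0 - r * r) ** 2
        return np.where(r < 1.0, w, 0.0)
    raise ValueError(f"unknown kernel {kernel!r}")


def fit_local_wls(X: np.ndarray, y: np.ndarray, w: np.ndarray,
                  ridge_eps: float = 1e-8) -> tuple[np.ndarray, bool]:
    """Solve one weighted least-squares system.

    Returns (coefficients, flagged); flagged is True when the weighted
    normal equations were singular within tolerance and a trace-scaled
    ridge was applied.
    """
    if np.sum(w) <= 0:
        raise ValueError("weights sum to zero")
    Xw = X * w[:, None]
    A = X.T @ Xw
    b = Xw.T @ y
    flagged = False
    try:
        beta = np.linalg.solve(A, b)
        if not np.all(np.isfinite(beta)) or np.max(np.abs(A @ beta - b)) > 1e-6 * (
                1.0 + np.max(np.abs(b))):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        flagged = True
        lam = ridge_eps * np.trace(A) / A.shape[0]
        beta = np.linalg.solve(A + (lam if lam > 0 else 1e-12) * np.eye(A.shape[0]), b)
    return beta, flagged


def _weight_matrix(D: np.ndarray, bandwidth: float, config: GTWRConfig) -> np.ndarray:
    if config.adaptive:
        k = int(bandwidth)
        if k < 2:
            raise ValueError("adaptive bandwidth (neighbour count) must be >= 2")
        # per-focal bandwidth: distance to the k-th nearest record
        part = np.partition(D, min(k, D.shape[1] - 1), axis=1)
        b_i = part[:, min(k, D.shape[1] - 1)]
        b_i = np.maximum(b_i, 1e-12)
        return kernel_weight(D / b_i[:, None], 1.0, config.kernel)
    return kernel_weight(D, bandwidth, config.kernel)


def _batched_fit(X: np.ndarray, y: np.ndarray, W: np.ndarray,
                 ridge_eps: float, need_hat: bool = False):
    """All local WLS fits at once.

    A_i = sum_j w_ij x_j x_j^T is assembled for every focal record i with
    one matrix product over flattened outer products, then solved with
    batched LAPACK.  Rows whose system is singular are refit with a ridge
    and flagged.

    Returns (betas (n, p1), flagged (n,), hat_diag or None).
    """
    n, p1 = X.shape
    O = (X[:, :, None] * X[:, None, :]).reshape(n, p1 * p1)
    A = (W @ O).reshape(n, p1, p1)
    b = W @ (X * y[:, None])
    flagged = np.zeros(n, dtype=bool)
    try:
        betas = np.linalg.solve(A, b[:, :, None])[:, :, 0]
    except np.linalg.LinAlgError:
        betas = np.full((n, p1), np.nan)
    resid_norm = np.abs(np.einsum("nij,nj->ni", A, np.nan_to_num(betas)) - b).max(axis=1)
    bad = ~np.isfinite(betas).all(axis=1) | (resid_norm > 1e-6 * (1.0 + np.abs(b).max()))
    for i in np.flatnonzero(bad):
        betas[i], fl = fit_local_wls(X, y, W[i], ridge_eps)
        flagged[i] = True
    hat = None
    if need_hat:
        # S_ii = w_ii * x_i^T A_i^{-1} x_i
        Ainv_x = np.linalg.solve(
            A + np.where(flagged, 1e-12, 0.0)[:, None, None] * np.eye(p1), X[:, :, None]
        )[:, :, 0]
        hat = np.einsum("ni,ni->n", X, Ainv_x) * np.diag(W)
    return betas, flagged, hat


def loocv_score(panel: PanelDataset, config: GTWRConfig, bandwidth: float,
                D: np.ndarray | None = None) -> float:
    """Leave-one-out CV score sum_i (y_i - yhat_(i))^2 at one bandwidth.

    The self-weight w_ii is forced to zero, which is algebraically the
    same as deleting record i and refitting.  Unsolvable records make the
    score +inf so bandwidth selection skips the candidate.
    """
    X = panel.design()
    y = panel.y()
    if panel.n < X.shape[1] + 1:
        raise ValueError("too few records for LOOCV")
    if D is None:
        D = st_distance_matrix(panel.points(), config.tau)
    W = _weight_matrix(D, bandwidth, config)
    np.fill_diagonal(W, 0.0)
    if np.any(W.sum(axis=1) < config.min_effective_weight):
        return np.inf
    try:
        betas, flagged, _ = _batched_fit(X, y, W, config.ridge_eps)
    except np.linalg.LinAlgError:
        return np.inf
    if flagged.any():
        return np.inf
    yhat = np.einsum("ij,ij->i", X, betas)
    if not np.all(np.isfinite(yhat)):
        return np.inf
    return float(np.sum((y - yhat) ** 2))


def _aicc(rss: float, n: int, trace_S: float) -> float:
    sigma2 = rss / n
    denom = n - 2.0 - trace_S
    if sigma2 <= 0 or denom <= 0:
        return np.inf
    return n * np.log(sigma2) + n * np.log(2 * np.pi) + n * (n + trace_S) / denom


def _criterion_score(panel, config, bandwidth, D) -> float:
    if config.criterion == "loocv":
        return loocv_score(panel, config, bandwidth, D)
    if config.criterion == "aicc":
        res = _fit_at(panel, config, bandwidth, D, need_hat=True)
        return res[5]
    raise ValueError(f"unknown criterion {config.criterion!r}")


def select_bandwidth(panel: PanelDataset, config: GTWRConfig,
                     D: np.ndarray | None = None) -> float:
    """Grid search plus golden-section refinement on the CV criterion.

    Ties on the grid go to the smaller bandwidth.  All-infinite scores
    (every candidate unsolvable) raise.
    """
    if D is None:
        D = st_distance_matrix(panel.points(), config.tau)
    grid = np.asarray(config.bandwidth_grid, dtype=float)
    if grid.size == 0:
        diam = float(D.max())
        grid = diam * np.array([0.02, 0.05, 0.1, 0.2, 0.4, 0.8])
    grid = np.sort(grid)
    scores = np.array([_criterion_score(panel, config, b, D) for b in grid])
    if not np.any(np.isfinite(scores)):
        raise ValueError("no solvable bandwidth candidate (all scores infinite)")
    k = int(np.flatnonzero(scores == scores.min())[0])  # ties -> smaller bandwidth
    if grid.size == 1:
        return float(grid[0])
    lo = grid[k - 1] if k > 0 else grid[0]
    hi = grid[k + 1] if k < grid.size - 1 else grid[-1]
    if hi <= lo:
        return float(grid[k])
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc = _criterion_score(panel, config, c, D)
    fd = _criterion_score(panel, config, d, D)
    for _ in range(20):
        if b - a < 1e-3 * (hi - lo):
            break
        if fc <= fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = _criterion_score(panel, config, c, D)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = _criterion_score(panel, config, d, D)
    cand = [(scores[k], grid[k]), (fc, c), (fd, d)]
    cand.sort(key=lambda t: (t[0], t[1]))
    return float(cand[0][1])


def _fit_at(panel, config, bandwidth, D, need_hat=True):
    X = panel.design()
    y = panel.y()
    W = _weight_matrix(D, bandwidth, config)
    betas, flagged, hat = _batched_fit(X, y, W, config.ridge_eps, need_hat=need_hat)
    eff = W.sum(axis=1) - np.diag(W)
    flagged |= eff < config.min_effective_weight
    yhat = np.einsum("ij,ij->i", X, betas)
    resid = y - yhat
    rss = float(np.sum(resid[~flagged] ** 2)) if (~flagged).any() else np.inf
    trace_S = float(np.sum(hat)) if hat is not None else np.nan
    aicc = _aicc(float(np.sum(resid**2)), len(y), trace_S) if need_hat else np.nan
    return betas, flagged, W, yhat, resid, aicc, trace_S


def fit_gtwr(panel: PanelDataset, config: GTWRConfig | None = None) -> GTWRResult:
    """Fit the full GTWR model: one local WLS per record.

    Bandwidth (and optionally the spatial/temporal scale ratio tau) are
    selected on the configured criterion when not fixed.  Deterministic
    given panel + config.  Raises when more than 10% of records remain
    unsolvable/flagged — the usual remedy is a larger bandwidth.
    """
    config = config or GTWRConfig()
    pts = panel.points()
    if config.lonlat:
        x, yk = lonlat_to_km(pts[:, 0], pts[:, 1])
        pts = np.column_stack([x, yk, pts[:, 2]])

    def distances(tau):
        return st_distance_matrix(pts, tau)

    if config.tau is None:
        best = (np.inf, None, None)
        for tau in config.tau_grid:
            sub = replace(config, tau=float(tau))
            D = distances(tau)
            bw = sub.bandwidth if sub.bandwidth is not None else select_bandwidth(panel, sub, D)
            score = _criterion_score(panel, sub, bw, D)
            if score < best[0]:
                best = (score, float(tau), float(bw))
        if best[1] is None:
            raise ValueError("tau selection failed: all candidates unsolvable")
        tau, bandwidth = best[1], best[2]
    else:
        tau = float(config.tau)
        D = distances(tau)
        bandwidth = (config.bandwidth if config.bandwidth is not None
                     else select_bandwidth(panel, replace(config, tau=tau), D))
    D = distances(tau)
    work = replace(config, tau=tau, bandwidth=float(bandwidth))
    betas, flagged, W, yhat, resid, aicc, trace_S = _fit_at(panel, work, bandwidth, D)
    n_flag = int(flagged.sum())
    if n_flag > 0.10 * panel.n:
        raise RuntimeError(
            f"{n_flag}/{panel.n} local systems unsolvable or under-weighted; "
            "increase the bandwidth")
    y = panel.y()
    X = panel.design()
    # local R^2: weighted goodness of fit of each local model in its own window
    pred = X @ betas.T                     # pred[j, i] = x_j . beta_i
    ybar_w = (W @ y) / W.sum(axis=1)
    rss_w = np.einsum("ij,ji->i", W, (y[:, None] - pred) ** 2)
    tss_w = np.einsum("ij,j->i", W, y * y) - W.sum(axis=1) * ybar_w**2
    with np.errstate(invalid="ignore", divide="ignore"):
        local_r2 = 1.0 - rss_w / tss_w
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else np.nan
    rmse = float(np.sqrt(np.mean(resid**2)))
    out = panel.frame[["unit_id", "year"]].copy()
    out["beta_0"] = betas[:, 0]
    for k, name in enumerate(panel.predictors, start=1):
        out[f"beta_{name}"] = betas[:, k]
    out["fitted"] = yhat
    out["residual"] = resid
    out["local_r2"] = local_r2
    out["flagged"] = flagged
    return GTWRResult(out, list(panel.predictors), r2, rmse, aicc, trace_S,
                      float(bandwidth), tau, work, n_flag)


def coefficient_summary(result: GTWRResult, group_by: str = "year") -> pd.DataFrame:
    """Distribution summaries of local coefficients.

    group_by="year": per-year quartiles/mean/whiskers of each coefficient
    across units (box-plot-ready).  group_by="unit": per-unit time-mean
    coefficients (map-ready).  Flagged records are excluded.
    """
    cols = ["beta_0"] + [f"beta_{p}" for p in result.predictors]
    frame = result.frame.loc[~result.frame["flagged"]]
    if group_by == "year":
        stats_ = frame.groupby("year")[cols].describe(percentiles=[0.25, 0.5, 0.75])
        stats_.columns = [f"{c[0]}_{c[1].replace('%', 'q')}" for c in stats_.columns]
        return stats_.reset_index()
    if group_by == "unit":
        return frame.groupby("unit_id")[cols].mean().reset_index()
    raise ValueError("group_by must be 'year' or 'unit'")
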
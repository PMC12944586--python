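"""Variance-inflation-factor screening of candidate drivers.

VIF_j = 1 / (1 - R_j^2), where R_j^2 comes from regressing predictor j on
all the other predictors (with intercept) over the pooled panel.  Drivers
with VIF above a threshold (7.5 here, a common remote-sensing-attribution
convention) are dropped before the local regression stage.  Screening is
single-pass by default: every variable over the threshold is removed at
once; an iterative mode (drop the worst, recompute, repeat) is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["VIFReport", "compute_vif", "screen"]

_R2_SINGULAR = 1.0 - 1e-12  # beyond this the auxiliary fit is numerically exact


@dataclass
class VIFReport:
    table: pd.DataFrame  # columns: variable, vif, excluded
    threshold: float

    def __getitem__(self, name: str) -> float:
        return float(self.table.set_index("variable").loc[name, "vif"])


def _aux_r2(X: np.ndarray, j: int) -> float:
    """R^2 of column j regressed on the other columns plus an intercept."""
    n = X.shape[0]
    others = np.delete(X, j, axis=1)
    design = np.column_stack([np.ones(n), others])
    y = X[:, j]
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0.0:
        raise ValueError(f"predictor column {j} has zero variance")
    return 1.0 - float(resid @ resid) / tss


def compute_vif(design, names: list[str] | None = None,
                threshold: float = 7.5) -> VIFReport:
    """VIF for every column of a predictor matrix (no intercept column).

    Exact collinearity is reported as a +inf sentinel, not an exception.
    """
    if isinstance(design, pd.DataFrame):
        names = list(design.columns)
        X = design.to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        if names is None:
            names = [f"x{j}" for j in range(X.shape[1])]
    if X.shape[1] < 2:
        raise ValueError("need >= 2 predictors for VIF")
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more records than predictors")
    vifs = []
    for j in range(X.shape[1]):
        r2 = _aux_r2(X, j)
        vifs.append(np.inf if r2 >= _R2_SINGULAR else 1.0 / (1.0 - r2))
    table = pd.DataFrame({
        "variable": names,
        "vif": vifs,
        "excluded": [v > threshold for v in vifs],
    })
    return VIFReport(table, threshold)


def screen(panel: pd.DataFrame, predictors: list[str], threshold: float = 7.5,
           iterative: bool = False) -> tuple[list[str], list[str], VIFReport]:
    """Apply the VIF > threshold exclusion rule to a pooled panel.

    Single-pass by default: excluded = {j : VIF_j > threshold} in one
    computation.  With ``iterative=True`` the largest-VIF variable is
    dropped and VIFs recomputed until all pass.

    Returns (retained, excluded, report); the report reflects the final
    VIF computation.
    """
    if threshold <= 1.0:
        raise ValueError("threshold must exceed 1")
    report = compute_vif(panel[predictors], threshold=threshold)
    if not iterative:
        excl = list(report.table.loc[report.table["excluded"], "variable"])
    else:
        remaining = list(predictors)
        excl = []
        while len(remaining) >= 2:
            report = compute_vif(panel[remaining], threshold=threshold)
            tab = report.table
            if not tab["excluded"].any():
                break
            worst = tab.loc[tab["vif"].idxmax(), "variable"]
            excl.append(worst)
            remaining.remove(worst)
    retained = [p for p in predictors if p not in excl]
    if not retained:
        raise ValueError("all predictors excluded by the VIF screen")
    return retained, excl, report
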
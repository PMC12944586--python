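"""Dominant-driver maps and dimension-averaged explanatory power.

Two summary products close the attribution analysis:

* per spatial unit, the *dominant factor*: the driver whose time-mean
  standardized GTWR coefficient has the largest absolute value, signed by
  its direction of effect ("GRGR+", "IR-", ...);
* per census year, the *dimension average*: the unweighted mean of the
  geographical-detector q-values over the factors of each dimension
  (natural / social / economic / policy), tracing how much of the spatial
  pattern each dimension explains over time.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .gtwr import GTWRResult

__all__ = [
    "DIMENSIONS",
    "DominantFactor",
    "dominant_factor",
    "dominant_factors",
    "dimension_average_q",
    "load_published_q_table",
]

# Factor -> dimension membership of the indicator set.
DIMENSIONS: dict[str, str] = {
    "MT": "natural", "MP": "natural", "MD": "natural", "MS": "natural",
    "PD": "social", "EPR": "social", "PI": "social", "FR": "social", "GY": "social",
    "PG": "economic", "PC": "economic", "IS": "economic", "IOR": "economic",
    "IR": "economic",
    "GRGR": "policy",
}


@dataclass(frozen=True)
class DominantFactor:
    unit_id: str
    factor: str
    sign: str            # "+" or "-"
    magnitude: float     # |time-mean standardized coefficient|
    tied: bool = False

    @property
    def label(self) -> str:
        return f"{self.factor}{self.sign}"


def _unit_means(result: GTWRResult) -> pd.DataFrame:
    frame = result.frame.loc[~result.frame["flagged"]]
    cols = [f"beta_{p}" for p in result.predictors]
    means = frame.groupby("unit_id")[cols].mean()
    means.columns = result.predictors
    return means


def _dominant_from_means(uid: str, row: pd.Series) -> DominantFactor:
    mags = row.abs()
    top = mags.max()
    winners = sorted(mags.index[np.isclose(mags, top, rtol=0, atol=0)])
    # exact ties broken lexicographically by factor name, flagged
    factor = winners[0]
    return DominantFactor(uid, factor, "+" if row[factor] >= 0 else "-",
                          float(top), tied=len(winners) > 1)


def dominant_factor(result: GTWRResult, unit: str, rule: str = "time_mean") -> DominantFactor:
    """Dominant driver for one unit.

    rule="time_mean" (default): largest |time-mean coefficient|;
    rule="final_year": largest |coefficient| in the unit's last year.
    Requires a model fitted on standardized variables for the comparison
    across factors to be meaningful.
    """
    if rule == "time_mean":
        means = _unit_means(result)
        if unit not in means.index:
            raise KeyError(f"unit {unit!r} not in fitted result")
        return _dominant_from_means(unit, means.loc[unit])
    if rule == "final_year":
        frame = result.frame.loc[~result.frame["flagged"]]
        sub = frame[frame["unit_id"] == unit]
        if sub.empty:
            raise KeyError(f"unit {unit!r} not in fitted result")
        last = sub.loc[sub["year"].idxmax()]
        row = pd.Series({p: last[f"beta_{p}"] for p in result.predictors})
        return _dominant_from_means(unit, row)
    raise ValueError(f"unknown dominance rule {rule!r}")


def dominant_factors(result: GTWRResult, rule: str = "time_mean") -> pd.DataFrame:
    """Dominant driver per unit, map-ready (unit_id, factor, sign, label, magnitude)."""
    units = result.frame["unit_id"].unique()
    rows = [dominant_factor(result, u, rule) for u in units]
    return pd.DataFrame([{
        "unit_id": d.unit_id, "factor": d.factor, "sign": d.sign,
        "label": d.label, "magnitude": d.magnitude, "tied": d.tied,
    } for d in rows])


def dimension_average_q(q_values: pd.DataFrame,
                        dims: dict[str, str] | None = None) -> pd.DataFrame:
    """Unweighted mean q per dimension per year.

    ``q_values`` is a factor x year table of q (NaN = factor unavailable
    that year, e.g. a policy ratio before the programme started); missing
    cells are excluded from the mean, and a dimension with no available
    factor in a year stays missing.  Returns a dimension x year frame.
    """
    dims = dims or DIMENSIONS
    if q_values.empty:
        raise ValueError("empty q table")
    unmapped = [f for f in q_values.index if f not in dims]
    if unmapped:
        raise ValueError(f"factors without a dimension: {unmapped}")
    groups = pd.Series({f: dims[f] for f in q_values.index}, name="dimension")
    return q_values.groupby(groups).mean()


def load_published_q_table() -> pd.DataFrame:
    """The reported factor-detector q matrix for the Yellow River Basin study.

    Rows are driver factors, columns census years (1980–2019); values are
    the published q-statistics of each driver for the spatial distribution
    of LAI (NaN where a factor was not yet defined).  Shipped as package
    data for worked-example checks of the dimension-average computation.
    """
    with resources.files("vegdrivers.data").joinpath("yrb_q_table.csv").open() as fh:
        tab = pd.read_csv(fh, index_col=0)
    tab.columns = tab.columns.astype(int)
    return tab
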
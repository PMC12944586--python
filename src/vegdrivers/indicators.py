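"""Driver-indicator construction and the Grain-for-Green policy ratio.

Socio-economic indicators are simple ratios of yearbook fields, each
normalised per capita or per unit area so cities of different sizes are
comparable:

    PD   population density                 persons / km^2
    EPR  employed / total population        dimensionless, in [0, 1]
    PI   fixed-asset investment per capita  currency / person
    FR   fiscal expenditure / revenue       dimensionless
    GY   grain output / sown grain area     kg / ha
    PG   GDP per capita                     currency / person
    PC   retail sales per capita            currency / person
    IS   tertiary GDP / secondary GDP       dimensionless
    IOR  GDP / fixed-asset investment       dimensionless
    IR   urban / rural income per capita    dimensionless

The policy-intensity variable GRGR is the ratio of cumulative
cropland-to-forest/shrub/grass conversion to baseline cropland, derived
from annual land-use class grids: cells cropland in EVERY baseline year
(1980–2000) are "permanent cropland"; cells ever converted during the
programme window (2001–2020) count cumulatively and never decrement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely import contains_xy
from shapely.geometry import shape as shapely_shape

from .grids import LandUseSeries, cell_centres

log = logging.getLogger(__name__)

__all__ = [
    "INDICATOR_DEFS",
    "compute_indicators",
    "permanent_cropland_mask",
    "zone_cell_index",
    "compute_grgr",
    "standardize_panel",
    "Standardizer",
]

# indicator -> (numerator field, denominator field)
INDICATOR_DEFS: dict[str, tuple[str, str]] = {
    "PD": ("population_total", "area_km2"),
    "EPR": ("population_employed", "population_total"),
    "PI": ("fixed_asset_investment", "population_total"),
    "FR": ("fiscal_expenditure", "fiscal_revenue"),
    "GY": ("grain_output_kg", "sown_grain_area_ha"),
    "PG": ("gdp", "population_total"),
    "PC": ("retail_sales", "population_total"),
    "IS": ("gdp_tertiary", "gdp_secondary"),
    "IOR": ("gdp", "fixed_asset_investment"),
    "IR": ("urban_income", "rural_income"),
}


def compute_indicators(records: pd.DataFrame) -> pd.DataFrame:
    """Build the ratio indicators from raw yearbook-style records.

    Records with a zero or missing denominator for some indicator get NaN
    for that indicator, are counted in the log, and keep their other
    indicators.  Returns one row per (unit_id, year).
    """
    need = {"unit_id", "year"} | {f for pair in INDICATOR_DEFS.values() for f in pair}
    missing = need - set(records.columns)
    if missing:
        raise ValueError(f"raw records missing columns: {sorted(missing)}")
    for col in need - {"unit_id", "year"}:
        if (records[col] < 0).any():
            raise ValueError(f"negative values in {col!r}")
    out = records[["unit_id", "year"]].copy()
    for name, (num, den) in INDICATOR_DEFS.items():
        d = records[den].to_numpy(dtype=float)
        bad = ~(d > 0)
        if bad.any():
            log.warning("%s: %d record(s) with zero denominator %s excluded",
                        name, int(bad.sum()), den)
        with np.errstate(divide="ignore", invalid="ignore"):
            val = records[num].to_numpy(dtype=float) / d
        out[name] = np.where(bad, np.nan, val)
    return out


def permanent_cropland_mask(lu: LandUseSeries, baseline_years) -> np.ndarray:
    """Cells classified cropland in EVERY baseline year (strict conjunction)."""
    baseline_years = list(baseline_years)
    missing = [y for y in baseline_years if y not in lu.years]
    if missing:
        raise ValueError(f"baseline years missing from land-use series: {missing}")
    crop = np.array(lu.codes_for("cropland"))
    mask = np.ones(lu.shape, dtype=bool)
    for y in baseline_years:
        mask &= np.isin(lu.grid(y), crop)
    return mask


def zone_cell_index(zones: list[dict], shape, origin=(0.0, 0.0),
                    cell_size: float = 1.0) -> dict[str, np.ndarray]:
    """Map each unit id to the boolean grid of cells whose centre it contains."""
    xs, ys = cell_centres(shape, origin, cell_size)
    out = {}
    for feat in zones:
        geom = shapely_shape(feat["geometry"])
        uid = feat["properties"]["unit_id"]
        out[uid] = contains_xy(geom, xs, ys)
    return out


def compute_grgr(lu: LandUseSeries, mask: np.ndarray, zones: list[dict],
                 years=None, baseline_years=None, window=(2001, 2020),
                 denominator: str = "baseline_union") -> pd.DataFrame:
    """Per-unit cumulative conversion ratio, per target year.

    Numerator: permanent-cropland cells in the zone that have EVER been
    forest/shrubland/grassland in a programme-window year <= the target
    year (monotone cumulative; reversion does not decrement).
    Denominator options: "baseline_union" (cells cropland in ANY baseline
    year — the default reading of "total cropland area"), or
    "permanent_only" (the permanent-cropland mask itself).

    Zones with a zero denominator get NaN with a log entry.  Returns a
    tidy frame (unit_id, year, GRGR) with GRGR nondecreasing per unit.
    """
    if years is None:
        years = [y for y in lu.years if y >= window[0]]
    years = sorted(years)
    if min(years) < window[0]:
        raise ValueError(f"target year {min(years)} precedes the programme window {window}")
    veg = np.array(lu.codes_for("forest", "shrubland", "grassland"))
    crop = np.array(lu.codes_for("cropland"))

    if denominator == "permanent_only" or baseline_years is None:
        denom_mask = mask
    elif denominator == "baseline_union":
        denom_mask = np.zeros(lu.shape, dtype=bool)
        for y in baseline_years:
            denom_mask |= np.isin(lu.grid(y), crop)
    else:
        raise ValueError(f"unknown denominator rule {denominator!r}")

    zone_masks = zone_cell_index(zones, lu.shape, lu.origin, lu.cell_size)
    window_years = [y for y in lu.years if window[0] <= y <= window[1]]

    rows = []
    ever = np.zeros(lu.shape, dtype=bool)
    wi = 0
    for yr in years:
        while wi < len(window_years) and window_years[wi] <= yr:
            ever |= np.isin(lu.grid(window_years[wi]), veg)
            wi += 1
        converted = ever & mask
        for uid, zmask in zone_masks.items():
            den = int((denom_mask & zmask).sum())
            if den == 0:
                log.warning("unit %s: zero cropland denominator; GRGR undefined", uid)
                rows.append({"unit_id": uid, "year": yr, "GRGR": np.nan})
            else:
                rows.append({"unit_id": uid, "year": yr,
                             "GRGR": (converted & zmask).sum() / den})
    return pd.DataFrame(rows)


@dataclass
class Standardizer:
    """Stored z-score parameters for an exact inverse mapping."""

    means: pd.Series
    sds: pd.Series

    def transform(self, frame: pd.DataFrame) -> pd.DataFrame:
        out = frame.copy()
        for c in self.means.index:
            out[c] = (frame[c] - self.means[c]) / self.sds[c]
        return out

    def inverse(self, frame: pd.DataFrame) -> pd.DataFrame:
        out = frame.copy()
        for c in self.means.index:
            out[c] = frame[c] * self.sds[c] + self.means[c]
        return out


def standardize_panel(frame: pd.DataFrame, columns: list[str]):
    """Z-score the given columns over all unit-years.

    Returns (standardized frame, Standardizer).  A zero-variance column
    is an error (it cannot carry information into the regression).
    """
    sds = frame[columns].std(ddof=0)
    zero = sds.index[sds == 0].tolist()
    if zero:
        raise ValueError(f"zero-variance column(s): {zero}")
    sc = Standardizer(frame[columns].mean(), sds)
    return sc.transform(frame), sc
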
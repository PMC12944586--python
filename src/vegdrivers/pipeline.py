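"""One-command orchestration of the full attribution analysis.

Stage order: synthesise inputs (panel / trend raster / land-use stack /
zones) -> raster trend products -> policy-ratio (GRGR) construction ->
panel standardisation -> VIF screen -> GTWR fit and coefficient
summaries -> dominant factors -> factor-detector q table -> dimension
averages.  Every output is a text file under the run directory and a JSON
manifest records parameters, the seed, package version and the SHA-256 of
each output, so a run is reproducible from the manifest plus the config.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as vio
from .attribution import DIMENSIONS, dimension_average_q, dominant_factors
from .geodetector import factor_detector_table
from .gtwr import GTWRConfig, PanelDataset, coefficient_summary, fit_gtwr
from .indicators import compute_grgr, permanent_cropland_mask, standardize_panel
from .synthetic import (SyntheticLanduseConfig, SyntheticRasterConfig,
                        generate_landuse_series, generate_panel,
                        generate_trend_raster, generate_zones,
                        standard_panel_config)
from .trends import area_fractions, classify_raster, raster_trends, segment_rates

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    out_dir: str = "results/run"
    seed: int = 0
    n_units: int = 50
    years: tuple[int, int] = (1980, 2019)
    panel_noise_sd: float = 0.1
    alpha: float = 0.05
    split_year: int = 2000
    vif_threshold: float = 7.5
    baseline_years: tuple[int, int] = (1980, 2000)
    conversion_window: tuple[int, int] = (2001, 2020)
    detector_years: tuple[int, ...] = (1980, 1990, 2000, 2010, 2019)
    detector_strata: int = 5
    detector_method: str = "quantile"
    detector_B: int = 199
    raster_shape: tuple[int, int] = (60, 60)
    landuse_shape: tuple[int, int] = (100, 100)
    gtwr_tau: float | None = 1.0
    gtwr_bandwidth: float | None = None
    gtwr_bandwidth_grid: tuple = (100.0, 200.0, 400.0)
    gtwr_kernel: str = "gaussian"
    standardize: bool = True
    stages: tuple[str, ...] = ("trends", "grgr", "vif", "gtwr", "detector")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("years", "baseline_years", "conversion_window", "detector_years",
                    "raster_shape", "landuse_shape", "gtwr_bandwidth_grid", "stages"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _save_csv(frame: pd.DataFrame, path: Path, manifest: dict, **kw) -> None:
    frame.to_csv(path, index=kw.pop("index", False), float_format="%.12g", **kw)
    manifest["outputs"][path.name] = vio.sha256_of(path)


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages on synthetic inputs; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": dataclasses.asdict(config),
        "outputs": {},
        "stages_completed": [],
        "failed_stage": None,
    }
    try:
        _run_stages(config, out, manifest)
    except Exception as exc:  # record partial completion before re-raising
        manifest["failed_stage"] = manifest.get("_current_stage")
        manifest["error"] = str(exc)
        _write_manifest(out, manifest)
        raise
    _write_manifest(out, manifest)
    return manifest


def _write_manifest(out: Path, manifest: dict) -> None:
    manifest.pop("_current_stage", None)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))


def _run_stages(config: RunConfig, out: Path, manifest: dict) -> None:
    y0, y1 = config.years

    # --- synthetic inputs ------------------------------------------------
    manifest["_current_stage"] = "synth"
    lu_cfg = SyntheticLanduseConfig(shape=config.landuse_shape,
                                    years=(y0, config.conversion_window[1]),
                                    seed=config.seed)
    lu = generate_landuse_series(lu_cfg)
    zones = generate_zones(config.n_units, lu.shape, origin=lu.origin,
                           cell_size=lu.cell_size)
    vio.write_zones(zones, out / "zones.geojson")
    manifest["outputs"]["zones.geojson"] = vio.sha256_of(out / "zones.geojson")

    baseline = range(config.baseline_years[0], config.baseline_years[1] + 1)
    mask = permanent_cropland_mask(lu, [y for y in baseline if y in lu.years])
    grgr = compute_grgr(lu, mask, zones,
                        years=[y for y in range(config.conversion_window[0], y1 + 1)],
                        baseline_years=[y for y in baseline if y in lu.years],
                        window=config.conversion_window)

    # GRGR before the programme window is identically zero, by definition
    pre = [{"unit_id": u, "year": yr, "GRGR": 0.0}
           for u in sorted(grgr["unit_id"].unique())
           for yr in range(y0, config.conversion_window[0])]
    grgr_full = pd.concat([pd.DataFrame(pre), grgr], ignore_index=True)

    pcfg = standard_panel_config(seed=config.seed, noise_sd=config.panel_noise_sd,
                                 with_collinear=True)
    pcfg = dataclasses.replace(pcfg, n_units=config.n_units, years=config.years,
                               external_values=grgr_full)
    panel, truth = generate_panel(pcfg)
    vio.write_panel(panel, out / "panel.csv")
    manifest["outputs"]["panel.csv"] = vio.sha256_of(out / "panel.csv")
    _save_csv(truth.frame, out / "panel_truth.csv", manifest)
    _save_csv(grgr_full, out / "grgr.csv", manifest)
    manifest["stages_completed"].append("synth")

    # --- raster trend products -------------------------------------------
    if "trends" in config.stages:
        manifest["_current_stage"] = "trends"
        rcfg = SyntheticRasterConfig(shape=config.raster_shape, years=config.years,
                                     seed=config.seed)
        raster = generate_trend_raster(rcfg)
        slope, p, _ = raster_trends(raster.stack, raster.years)
        classes = classify_raster(slope, p, config.alpha)
        fracs = area_fractions(classes)
        _save_csv(pd.DataFrame([{ "trend_class": k.value, "fraction": v}
                                for k, v in fracs.items()]),
                  out / "trend_fractions.csv", manifest)
        mean_series = raster.stack.reshape(len(raster.years), -1).mean(axis=1)
        pre_fit, post_fit = segment_rates(raster.years, mean_series, config.split_year)
        _save_csv(pd.DataFrame([
            {"segment": f"{y0}-{config.split_year}", "slope": pre_fit.slope,
             "p_value": pre_fit.p_value},
            {"segment": f"{config.split_year}-{y1}", "slope": post_fit.slope,
             "p_value": post_fit.p_value}]),
            out / "trend_rates.csv", manifest)
        manifest["stages_completed"].append("trends")

    # --- standardisation + VIF screen -------------------------------------
    frame = panel.frame.copy()
    predictors = list(panel.predictors)
    if config.standardize:
        frame, scaler = standardize_panel(frame, predictors)
        manifest["standardization"] = {
            "means": {k: float(v) for k, v in scaler.means.items()},
            "sds": {k: float(v) for k, v in scaler.sds.items()}}
    retained = predictors
    if "vif" in config.stages:
        manifest["_current_stage"] = "vif"
        from .vif import screen
        retained, excluded, report = screen(frame, predictors, config.vif_threshold)
        _save_csv(report.table, out / "vif.csv", manifest)
        manifest["vif_excluded"] = excluded
        manifest["stages_completed"].append("vif")

    # --- GTWR --------------------------------------------------------------
    if "gtwr" in config.stages:
        manifest["_current_stage"] = "gtwr"
        gconf = GTWRConfig(kernel=config.gtwr_kernel, tau=config.gtwr_tau,
                           bandwidth=config.gtwr_bandwidth,
                           bandwidth_grid=config.gtwr_bandwidth_grid)
        result = fit_gtwr(PanelDataset(frame, retained), gconf)
        _save_csv(result.frame, out / "gtwr_coefficients.csv", manifest)
        _save_csv(coefficient_summary(result, "year"), out / "gtwr_by_year.csv", manifest)
        _save_csv(coefficient_summary(result, "unit"), out / "gtwr_by_unit.csv", manifest)
        dom = dominant_factors(result)
        _save_csv(dom, out / "dominant_factors.csv", manifest)
        manifest["gtwr"] = {"bandwidth": result.bandwidth, "tau": result.tau,
                            "r2": result.r2, "rmse": result.rmse,
                            "n_flagged": result.n_flagged}
        manifest["stages_completed"].append("gtwr")

    # --- geographical detector --------------------------------------------
    if "detector" in config.stages:
        manifest["_current_stage"] = "detector"
        det_frame = frame.copy()
        det_frame.loc[det_frame["year"] < config.conversion_window[0], "GRGR"] = np.nan
        years = [y for y in config.detector_years if y0 <= y <= y1]
        factors = [f for f in predictors if f in DIMENSIONS]
        table = factor_detector_table(det_frame, panel.response, factors, years,
                                      L=config.detector_strata,
                                      method=config.detector_method,
                                      B=config.detector_B, seed=config.seed)
        q_only = table.xs("q", axis=1, level="stat")
        flat = table.copy()
        flat.columns = [f"{yr}_{stat}" for yr, stat in table.columns]
        _save_csv(flat.reset_index(names="factor"), out / "q_table.csv", manifest)
        dim_avg = dimension_average_q(q_only)
        _save_csv(dim_avg.reset_index(), out / "dimension_q.csv", manifest)
        manifest["stages_completed"].append("detector")
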
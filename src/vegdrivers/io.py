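"""Readers and writers for the pipeline's on-disk formats.

Everything is plain text: panels and tables as CSV with a one-line schema
header, raster stacks as ESRI ASCII grids (one ``.asc`` per year plus a
JSON sidecar for years / class codes), zones as GeoJSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import LandUseSeries, RasterSeries
from .gtwr import PanelDataset

log = logging.getLogger(__name__)

SCHEMA_HEADER = "# vegdrivers-panel v1"

__all__ = [
    "write_panel", "read_panel",
    "write_ascii_grid", "read_ascii_grid",
    "write_raster_stack", "read_raster_stack",
    "write_landuse_stack", "read_landuse_stack",
    "write_zones", "read_zones",
    "sha256_of",
]


def write_panel(panel: PanelDataset, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(SCHEMA_HEADER + "\n")
        fh.write("# predictors: " + ",".join(panel.predictors) + "\n")
        panel.frame.to_csv(fh, index=False, float_format="%.12g")


def read_panel(path, response: str = "response",
               predictors: list[str] | None = None) -> PanelDataset:
    """Read a panel CSV; malformed rows and missing-response rows are
    dropped with a logged count; a missing required column is a schema
    error naming it."""
    path = Path(path)
    if predictors is None:
        predictors = []
        with path.open() as fh:
            for line in fh:
                if line.startswith("# predictors:"):
                    predictors = [s for s in line.split(":", 1)[1].strip().split(",") if s]
                if not line.startswith("#"):
                    break
    bad = []
    frame = pd.read_csv(path, comment="#", engine="python",
                        on_bad_lines=lambda row: bad.append(row) and None)
    if frame.empty and not frame.columns.size:
        raise ValueError(f"{path}: empty file, no panel schema")
    required = ["unit_id", "x_km", "y_km", "year", response, *predictors]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if bad:
        log.warning("%s: dropped %d malformed row(s)", path, len(bad))
    n0 = len(frame)
    frame = frame.dropna(subset=[response]).reset_index(drop=True)
    if len(frame) < n0:
        log.warning("%s: dropped %d row(s) with missing response", path, n0 - len(frame))
    return PanelDataset(frame, predictors, response)


def write_ascii_grid(grid: np.ndarray, path, origin=(0.0, 0.0), cell_size: float = 1.0,
                     nodata: float = -9999.0) -> None:
    """ESRI ASCII grid, north-up; NaNs become the nodata value."""
    grid = np.asarray(grid, dtype=float)
    rows, cols = grid.shape
    x0, ytop = origin
    out = np.where(np.isfinite(grid), grid, nodata)
    with Path(path).open("w") as fh:
        fh.write(f"ncols {cols}\nnrows {rows}\n")
        fh.write(f"xllcorner {x0:.10g}\nyllcorner {ytop - rows * cell_size:.10g}\n")
        fh.write(f"cellsize {cell_size:.10g}\nNODATA_value {nodata:.10g}\n")
        np.savetxt(fh, out, fmt="%.10g")


def read_ascii_grid(path) -> tuple[np.ndarray, tuple[float, float], float]:
    """Returns (grid with NaN nodata, top-left origin, cell size)."""
    head: dict[str, float] = {}
    with Path(path).open() as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            head[key.lower()] = float(val)
        grid = np.loadtxt(fh)
    rows = int(head["nrows"])
    cols = int(head["ncols"])
    grid = grid.reshape(rows, cols)
    nodata = head.get("nodata_value")
    if nodata is not None:
        grid = np.where(grid == nodata, np.nan, grid)
    cs = head["cellsize"]
    origin = (head["xllcorner"], head["yllcorner"] + rows * cs)
    return grid, origin, cs


def write_raster_stack(series: RasterSeries, out_dir, prefix: str = "band") -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, yr in enumerate(series.years):
        p = out_dir / f"{prefix}_{yr}.asc"
        write_ascii_grid(series.stack[i], p, series.origin, series.cell_size)
        paths.append(p)
    (out_dir / f"{prefix}_years.json").write_text(json.dumps({"years": series.years}))
    return paths


def read_raster_stack(paths, years) -> RasterSeries:
    """Stack per-year grids; shapes and georeference must agree."""
    paths = [Path(p) for p in paths]
    if len(paths) != len(years):
        raise ValueError(f"{len(paths)} band file(s) but {len(years)} year(s)")
    grids, origins, sizes = [], [], []
    for p in paths:
        g, o, cs = read_ascii_grid(p)
        grids.append(g)
        origins.append(o)
        sizes.append(cs)
    shapes = {g.shape for g in grids}
    if len(shapes) > 1:
        offender = next(p for p, g in zip(paths, grids) if g.shape != grids[0].shape)
        raise ValueError(f"band shape mismatch at {offender}")
    return RasterSeries(np.stack(grids), list(years), origins[0], sizes[0])


def write_landuse_stack(lu: LandUseSeries, out_dir, prefix: str = "landuse") -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for i, yr in enumerate(lu.years):
        write_ascii_grid(lu.stack[i].astype(float), out_dir / f"{prefix}_{yr}.asc",
                         lu.origin, lu.cell_size)
    sidecar = {"years": lu.years, "class_table": {str(k): v for k, v in lu.class_table.items()}}
    (out_dir / f"{prefix}_classes.json").write_text(json.dumps(sidecar, indent=1))


def read_landuse_stack(in_dir, prefix: str = "landuse") -> LandUseSeries:
    in_dir = Path(in_dir)
    sidecar = json.loads((in_dir / f"{prefix}_classes.json").read_text())
    years = sidecar["years"]
    table = {int(k): v for k, v in sidecar["class_table"].items()}
    grids, origin, cs = [], (0.0, 0.0), 1.0
    for yr in years:
        g, origin, cs = read_ascii_grid(in_dir / f"{prefix}_{yr}.asc")
        grids.append(np.nan_to_num(g).astype(int))
    return LandUseSeries(np.stack(grids), years, table, origin, cs)


def write_zones(features: list[dict], path) -> None:
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": features}, indent=1))


def read_zones(path) -> list[dict]:
    fc = json.loads(Path(path).read_text())
    feats = fc["features"]
    for f in feats:
        if "unit_id" not in f.get("properties", {}):
            raise ValueError(f"{path}: feature without a unit_id property")
    return feats


def sha256_of(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
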
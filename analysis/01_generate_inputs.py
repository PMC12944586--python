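#!/usr/bin/env python
"""Generate the study-shaped synthetic inputs.

Builds the three inputs every later stage consumes, at the study's
conditions — a 50-city x 40-year (1980-2019) driver panel whose response
follows known affine coefficient surfaces, a 100x100 annual LAI raster
with 57% of cells trending upward (11% strongly), and a 1980-2020 land-use
stack whose cropland-conversion schedule ramps up after 2005 — and writes
them as text (CSV / ASCII grids / GeoJSON) under results/inputs/.
"""

from pathlib import Path

from vegdrivers import io as vio
from vegdrivers.synthetic import (SyntheticLanduseConfig, SyntheticRasterConfig,
                                  generate_landuse_series, generate_panel,
                                  generate_trend_raster, generate_zones,
                                  standard_panel_config)

SEED = 0
ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results" / "inputs"
SCRATCH = ROOT / "scratch" / "inputs"   # bulky regenerable files live here


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)

    panel, truth = generate_panel(standard_panel_config(seed=SEED, with_collinear=True))
    vio.write_panel(panel, SCRATCH / "panel.csv")
    truth.frame.to_csv(SCRATCH / "panel_truth.csv", index=False, float_format="%.8g")
    panel.frame.describe().T.to_csv(OUT / "panel_summary.csv", float_format="%.4g")
    print(f"panel: {panel.n} unit-year records, "
          f"{len(panel.predictors)} candidate drivers -> {SCRATCH / 'panel.csv'}")

    raster = generate_trend_raster(SyntheticRasterConfig(seed=SEED))
    # keep only the label grid (the ground truth later stages must recover);
    # the 40-band stack itself is regenerated from the seed where needed
    vio.write_ascii_grid(raster.labels.astype(float), OUT / "raster_labels.asc")
    print(f"trend raster: {raster.shape} cells x {len(raster.years)} years, "
          f"{(raster.labels > 0).mean():.0%} built increasing")

    lu = generate_landuse_series(SyntheticLanduseConfig(shape=(60, 60), seed=SEED))
    # keep the tree small: persist only the final-year class grid as a sample;
    # downstream stages regenerate the full stack from the same seed
    vio.write_ascii_grid(lu.stack[-1].astype(float), OUT / "landuse_2020.asc")
    zones = generate_zones(50, lu.shape, cell_size=lu.cell_size)
    vio.write_zones(zones, OUT / "zones.geojson")
    print(f"land use: {lu.shape} cells, years {lu.years[0]}-{lu.years[-1]}, "
          f"{len(zones)} unit zones -> {OUT / 'zones.geojson'}")


if __name__ == "__main__":
    main()
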
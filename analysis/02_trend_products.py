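#!/usr/bin/env python
"""Vegetation trend products: per-cell slopes, significance classes,
area fractions, and the before/after-2000 segment rates.

On the synthetic LAI raster (built with 57% increasing cells, 11%
strongly increasing) the per-cell OLS trend + t-test classification
recovers the constructed fractions; the basin-mean trajectory is split at
the policy year 2000 into two independently fitted segments.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from vegdrivers.synthetic import SyntheticRasterConfig, generate_trend_raster
from vegdrivers.trends import (area_fractions, classify_raster, raster_trends,
                               segment_rates)

SEED = 0
OUT = Path(__file__).resolve().parent.parent / "results" / "trends"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    raster = generate_trend_raster(SyntheticRasterConfig(seed=SEED))

    slope, p, _ = raster_trends(raster.stack, raster.years)
    classes = classify_raster(slope, p, alpha=0.05)
    fracs = area_fractions(classes)
    tab = pd.DataFrame([{"trend_class": k.value, "fraction": v}
                        for k, v in fracs.items()])
    tab.to_csv(OUT / "area_fractions.csv", index=False, float_format="%.4f")
    inc = tab.loc[tab.trend_class.str.endswith("inc"), "fraction"].sum()
    built = (raster.labels > 0).mean()
    print(f"increasing area: {inc:.1%} recovered (built {built:.1%})")
    print(tab.to_string(index=False))

    # basin-mean trajectory: a slow pre-2000 rise accelerating after the
    # policy year, plus observation noise; the segment fits recover the rates
    rng = np.random.default_rng(SEED)
    years = np.arange(1980, 2020)
    mean_series = np.where(years <= 2000, 1.0 + 0.0028 * (years - 1980),
                           1.0 + 0.0028 * 20 + 0.0123 * (years - 2000))
    mean_series = mean_series + rng.normal(0, 0.005, years.size)
    pre, post = segment_rates(years, mean_series, split_year=2000)
    rates = pd.DataFrame([
        {"segment": "1980-2000", "slope_per_year": pre.slope, "p_value": pre.p_value},
        {"segment": "2000-2019", "slope_per_year": post.slope, "p_value": post.p_value}])
    rates.to_csv(OUT / "segment_rates.csv", index=False, float_format="%.6g")
    print(f"basin-mean rate before 2000: {pre.slope:.4f}/yr, "
          f"after 2000: {post.slope:.4f}/yr")


if __name__ == "__main__":
    main()
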
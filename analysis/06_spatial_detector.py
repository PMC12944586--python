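#!/usr/bin/env python
"""Explanatory power of drivers for the spatial LAI pattern.

Runs the factor detector (q = 1 - SSW/SST, quantile stratification L=5,
permutation significance) on the synthetic panel for the five census
years, averages q by dimension, and reproduces the dimension averages of
the published q matrix as a worked example.
"""

from pathlib import Path

from vegdrivers.attribution import (DIMENSIONS, dimension_average_q,
                                    load_published_q_table)
from vegdrivers.geodetector import factor_detector_table
from vegdrivers.synthetic import generate_panel, standard_panel_config

SEED = 0
YEARS = [1980, 1990, 2000, 2010, 2019]
OUT = Path(__file__).resolve().parent.parent / "results" / "detector"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    panel, _ = generate_panel(standard_panel_config(seed=SEED, with_collinear=True))
    factors = [f for f in panel.predictors if f in DIMENSIONS]
    tab = factor_detector_table(panel.frame, "response", factors, YEARS,
                                L=5, method="quantile", B=999, seed=SEED)
    flat = tab.copy()
    flat.columns = [f"{yr}_{stat}" for yr, stat in tab.columns]
    flat.reset_index(names="factor").to_csv(OUT / "q_table.csv", index=False,
                                            float_format="%.4g")
    q_only = tab.xs("q", axis=1, level="stat")
    dim = dimension_average_q(q_only)
    dim.to_csv(OUT / "dimension_q_synthetic.csv", float_format="%.4g")
    print("dimension-average q on the synthetic panel:")
    print(dim.to_string(float_format="%.3f"))

    pub = dimension_average_q(load_published_q_table())
    pub.to_csv(OUT / "dimension_q_published.csv", float_format="%.5g")
    print("\ndimension-average q of the published factor-detector matrix:")
    print(pub.to_string(float_format="%.4f"))
    print("\nnatural factors stay in the 0.4-0.5 band; the policy ratio "
          "reaches %.2f by 2019." % pub.loc["policy", 2019])


if __name__ == "__main__":
    main()
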
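# vegdrivers

Attribution of vegetation change to natural, social, economic and policy
drivers, for landscape ecologists working at the administrative-unit
scale.  The package implements the full analysis chain used to explain
multi-decadal leaf-area-index (LAI) dynamics over a set of cities:

1. **Trend products** — per-pixel OLS slopes with t-test significance,
   four-way trend classes, area fractions, and before/after-breakpoint
   segment rates.
2. **Indicator construction** — yearbook ratios (population density,
   employment ratio, fiscal expenditure/revenue, grain yield, income
   ratio, ...) and a land-use-derived policy intensity: the
   Grain-for-Green ratio (cumulative cropland→forest/shrub/grass
   conversion over baseline cropland).
3. **Collinearity screen** — pooled-panel variance inflation factors with
   the VIF > 7.5 single-pass exclusion rule.
4. **GTWR** — geographically and temporally weighted regression,

   y_i = β₀(u_i,v_i,t_i) + Σ_k β_k(u_i,v_i,t_i) x_ik + ε_i,

   one weighted least-squares fit per unit-year with Gaussian kernel
   weights in the combined distance d² = Δu² + Δv² + τ·Δt², bandwidth and
   τ selected by leave-one-out cross-validation.
5. **Geographical detector** — the factor-detector statistic
   q = 1 − SSW/SST (population variances, so the decomposition is exact),
   quantile stratification, permutation significance; dominant-factor
   maps and dimension-averaged q trajectories close the analysis.

A synthetic-data module generates every input — a 50-city × 40-year
panel with known affine coefficient surfaces, trend rasters with a
controlled fraction of rising cells, land-use stacks with a scheduled
conversion programme — so the whole chain is testable without any
external data.  See `docs/methods.md` for the model details and design
choices.

## Worked example

```python
from vegdrivers.synthetic import generate_panel, standard_panel_config
from vegdrivers.vif import screen
from vegdrivers.gtwr import GTWRConfig, PanelDataset, fit_gtwr
from vegdrivers.indicators import standardize_panel

panel, truth = generate_panel(standard_panel_config(seed=0, with_collinear=True))
retained, excluded, _ = screen(panel.frame, panel.predictors, threshold=7.5)
print(excluded)                      # ['PD', 'PI', 'PC', 'PG']

frame, _ = standardize_panel(panel.frame, retained)
result = fit_gtwr(PanelDataset(frame, retained), GTWRConfig())
print(round(result.bandwidth, 1), round(result.tau), round(result.r2, 3))
# 106.4 256 0.997
```

The four constructed near-collinear covariates are the ones the VIF
screen removes; the cross-validated fit settles on a ~106 km-equivalent
bandwidth with one year trading against 16 km (τ = 256 km²/yr²) and
explains 99.7 % of the response variance.  Per-unit dominant factors
then summarise the coefficient fields — on this panel 29 units are
dominated by temperature (MT+), 13 by the income ratio (IR−) and 8 by
the employment ratio (EPR+).

The analysis itself is organised as numbered drivers:

```sh
python analysis/01_generate_inputs.py      # synthetic panel/raster/land use
python analysis/02_trend_products.py       # slopes, classes, area fractions
python analysis/03_indicators_policy.py    # indicator ratios + GRGR
python analysis/04_collinearity_screen.py  # VIF table
python analysis/05_gtwr_attribution.py     # local coefficients, dominant factors
python analysis/06_spatial_detector.py     # q table, dimension averages
```

each printing what it found and writing its tables under `results/`.
For example, `02` recovers an increasing-area fraction of 57.0 % from a
raster built with 57 %, and segment rates of 0.0027/yr before and
0.0124/yr after the year-2000 breakpoint from a trajectory built with
0.0028 and 0.0123; `06` reduces the published factor-detector matrix to
dimension averages — natural factors stay in the 0.4–0.5 band across all
five census years while the policy ratio climbs to 0.31 by 2019.

A one-command orchestration with a JSON manifest (parameters, seed,
SHA-256 of every output) is available via
`vegdrivers.pipeline.run_pipeline` / `RunConfig.from_yaml`.

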
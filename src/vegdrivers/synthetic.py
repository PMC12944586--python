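"""Synthetic inputs with known ground truth for the attribution pipeline.

Three generators mirror the three kinds of input the analysis consumes:

* a city-level panel whose response follows the varying-coefficient model
  ``y_i = beta_0(u,v,t) + sum_k beta_k(u,v,t) x_ik + eps_i`` with affine
  coefficient surfaces ``beta_k = a + b u + c v + d (t - t0)`` — smooth
  enough for a local regression to track, simple enough for closed-form
  ground truth;
* an annual raster stack with a controlled fraction of (significantly)
  trending cells, for the trend-classification products;
* an annual land-use class stack with a controlled cropland-to-
  forest/shrub/grass conversion schedule, for the policy-intensity ratio.

One global seed feeds named substreams (panel / raster / landuse / zones)
so each product can be regenerated independently and reproducibly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import box, mapping

from .grids import LandUseSeries, RasterSeries
from .gtwr import PanelDataset

__all__ = [
    "PredictorSpec",
    "DerivedPredictorSpec",
    "SyntheticPanelConfig",
    "SyntheticRasterConfig",
    "SyntheticLanduseConfig",
    "CoefficientSurfaces",
    "generate_panel",
    "generate_trend_raster",
    "generate_landuse_series",
    "generate_zones",
    "generate_raw_stats",
    "standard_panel_config",
]

_SUBSTREAM = {"panel": 0, "raster": 1, "landuse": 2, "zones": 3, "rawstats": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _SUBSTREAM[stream]]))


@dataclass(frozen=True)
class PredictorSpec:
    """A predictor with its sampling moments and affine coefficient surface.

    ``surface`` = (a, b, c, d) gives beta(u, v, t) = a + b u + c v + d (t - t0)
    with u, v in km and t in years.
    """

    name: str
    mean: float = 0.0
    sd: float = 1.0
    surface: tuple[float, float, float, float] = (0.5, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class DerivedPredictorSpec:
    """A collinear covariate: a weighted sum of parents plus Gaussian noise.

    Derived predictors exist to exercise the multicollinearity screen;
    they carry no coefficient in the response model.
    """

    name: str
    parents: tuple[str, ...]
    weights: tuple[float, ...]
    noise_sd: float = 0.45


@dataclass
class SyntheticPanelConfig:
    n_units: int = 50
    years: tuple[int, int] = (1980, 2019)
    domain: tuple[float, float] = (1000.0, 800.0)     # x/y extent, km
    predictors: tuple[PredictorSpec, ...] = (
        PredictorSpec("x1", 0.0, 1.0, (0.5, 5e-4, -4e-4, 0.01)),
        PredictorSpec("x2", 0.0, 1.0, (-0.3, -4e-4, 6e-4, -0.008)),
        PredictorSpec("x3", 0.0, 1.0, (0.2, 6e-4, 5e-4, 0.012)),
    )
    derived: tuple[DerivedPredictorSpec, ...] = ()
    intercept_surface: tuple[float, float, float, float] = (1.5, 2e-4, -2e-4, 0.005)
    noise_sd: float = 0.1
    t0: int | None = None                              # default: first year
    jitter_frac: float = 0.05                          # jitter sd as fraction of grid spacing
    predictor_corr: float = 0.0                        # pairwise corr among base predictors
    # optional tidy frame (unit_id, year, <predictor> columns) whose values
    # replace the Gaussian draws for those predictors BEFORE the response is
    # generated — e.g. a policy ratio derived from a land-use stack
    external_values: pd.DataFrame | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_units < 5:
            raise ValueError(f"n_units={self.n_units}: need >= 5")
        if self.years[1] - self.years[0] < 2:
            raise ValueError(f"years={self.years}: span must cover >= 3 years")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd={self.noise_sd}: must be >= 0")
        if not -1.0 < self.predictor_corr < 1.0:
            raise ValueError(f"predictor_corr={self.predictor_corr}: must be in (-1, 1)")
        names = [p.name for p in self.predictors] + [d.name for d in self.derived]
        if len(set(names)) != len(names):
            raise ValueError("duplicate predictor names")
        for d in self.derived:
            if not set(d.parents) <= {p.name for p in self.predictors}:
                raise ValueError(f"derived predictor {d.name}: unknown parent")


@dataclass
class CoefficientSurfaces:
    """True coefficients per unit-year, aligned row-for-row with the panel.

    ``frame`` has unit_id, year, beta_0, beta_<name> per base predictor,
    plus the systematic part and the stored noise draw for each record.
    """

    frame: pd.DataFrame
    predictors: list[str]

    def beta(self, name: str) -> np.ndarray:
        return self.frame[f"beta_{name}"].to_numpy()


def _unit_coords(n_units: int, domain, jitter_frac: float, rng) -> np.ndarray:
    """Jittered regular grid of unit 'city centres' over the domain."""
    w, h = domain
    nx = int(np.ceil(np.sqrt(n_units * w / h)))
    ny = int(np.ceil(n_units / nx))
    sx, sy = w / nx, h / ny
    gx, gy = np.meshgrid(np.arange(nx), np.arange(ny))
    pts = np.column_stack([(gx.ravel() + 0.5) * sx, (gy.ravel() + 0.5) * sy])[:n_units]
    pts[:, 0] += rng.normal(0.0, jitter_frac * sx, n_units)
    pts[:, 1] += rng.normal(0.0, jitter_frac * sy, n_units)
    return pts


def generate_panel(config: SyntheticPanelConfig) -> tuple[PanelDataset, CoefficientSurfaces]:
    """Simulate the varying-coefficient panel and return it with its truth."""
    config.validate()
    rng = _rng(config.seed, "panel")
    y0, y1 = config.years
    years = np.arange(y0, y1 + 1)
    t0 = config.t0 if config.t0 is not None else y0
    coords = _unit_coords(config.n_units, config.domain, config.jitter_frac, rng)

    unit_idx = np.repeat(np.arange(config.n_units), years.size)
    year_col = np.tile(years, config.n_units)
    u = coords[unit_idx, 0]
    v = coords[unit_idx, 1]
    n = unit_idx.size
    p = len(config.predictors)

    if config.predictor_corr != 0.0:
        C = np.full((p, p), config.predictor_corr) + (1 - config.predictor_corr) * np.eye(p)
        Z = rng.multivariate_normal(np.zeros(p), C, size=n, method="cholesky")
    else:
        Z = rng.standard_normal((n, p))
    X = np.column_stack([spec.mean + spec.sd * Z[:, k]
                         for k, spec in enumerate(config.predictors)])

    if config.external_values is not None:
        ext = config.external_values
        key = pd.DataFrame({"unit_id": [f"U{idx:03d}" for idx in unit_idx],
                            "year": year_col})
        merged = key.merge(ext, on=["unit_id", "year"], how="left")
        for k, spec in enumerate(config.predictors):
            if spec.name in ext.columns:
                vals = merged[spec.name].to_numpy(dtype=float)
                if np.any(np.isnan(vals)):
                    raise ValueError(
                        f"external values for {spec.name!r} missing some unit-years")
                X[:, k] = vals

    def surface(coefs):
        a, b, c, d = coefs
        return a + b * u + c * v + d * (year_col - t0)

    beta0 = surface(config.intercept_surface)
    betas = np.column_stack([surface(s.surface) for s in config.predictors])
    systematic = beta0 + np.einsum("ij,ij->i", betas, X)
    eps = rng.normal(0.0, config.noise_sd, n) if config.noise_sd > 0 else np.zeros(n)
    response = systematic + eps

    frame = pd.DataFrame({
        "unit_id": [f"U{idx:03d}" for idx in unit_idx],
        "x_km": u, "y_km": v, "year": year_col, "response": response,
    })
    for k, spec in enumerate(config.predictors):
        frame[spec.name] = X[:, k]
    for d in config.derived:
        cols = np.column_stack([frame[p_].to_numpy() for p_ in d.parents])
        frame[d.name] = cols @ np.asarray(d.weights) + rng.normal(0, d.noise_sd, n)

    truth = pd.DataFrame({"unit_id": frame["unit_id"], "year": year_col, "beta_0": beta0})
    for k, spec in enumerate(config.predictors):
        truth[f"beta_{spec.name}"] = betas[:, k]
    truth["systematic"] = systematic
    truth["epsilon"] = eps

    names = [s.name for s in config.predictors] + [d.name for d in config.derived]
    panel = PanelDataset(frame, names)
    return panel, CoefficientSurfaces(truth, [s.name for s in config.predictors])


def standard_panel_config(seed: int = 0, noise_sd: float = 0.1,
                          with_collinear: bool = False) -> SyntheticPanelConfig:
    """The study-shaped panel: 50 cities x 40 years, nine driver factors.

    Factor names follow the attribution study's indicator set (MT, MP,
    EPR, FR, GY, IS, IOR, IR, GRGR); surfaces are distinct affine forms so
    each coefficient field is individually recoverable.  With
    ``with_collinear`` four additional covariates (PD, PI, PC, PG) are
    generated as noisy sums of two retained factors each, so a VIF > 7.5
    screen removes exactly those four.
    """
    specs = (
        PredictorSpec("MT", 0.0, 1.0, (0.45, 5.0e-4, -3.0e-4, 0.010)),
        PredictorSpec("MP", 0.0, 1.0, (0.60, -4.0e-4, 5.0e-4, -0.006)),
        PredictorSpec("EPR", 0.0, 1.0, (0.35, 6.0e-4, 4.0e-4, -0.008)),
        PredictorSpec("FR", 0.0, 1.0, (0.25, -5.0e-4, -4.0e-4, -0.005)),
        PredictorSpec("GY", 0.0, 1.0, (0.30, 7.0e-4, -5.0e-4, -0.007)),
        PredictorSpec("IS", 0.0, 1.0, (-0.20, 4.0e-4, 6.0e-4, 0.009)),
        PredictorSpec("IOR", 0.0, 1.0, (-0.30, -6.0e-4, 3.0e-4, 0.004)),
        PredictorSpec("IR", 0.0, 1.0, (-0.40, 5.0e-4, -6.0e-4, -0.009)),
        PredictorSpec("GRGR", 0.0, 1.0, (0.40, -3.0e-4, -5.0e-4, 0.012)),
    )
    derived = (
        DerivedPredictorSpec("PD", ("MT", "MP"), (1.0, 1.0)),
        DerivedPredictorSpec("PI", ("EPR", "FR"), (1.0, 1.0)),
        DerivedPredictorSpec("PC", ("GY", "IS"), (1.0, 1.0)),
        DerivedPredictorSpec("PG", ("IOR", "IR"), (1.0, 1.0)),
    ) if with_collinear else ()
    return SyntheticPanelConfig(predictors=specs, derived=derived,
                                noise_sd=noise_sd, seed=seed)


@dataclass
class SyntheticRasterConfig:
    shape: tuple[int, int] = (100, 100)
    years: tuple[int, int] = (1980, 2019)
    fraction_increasing: float = 0.57
    fraction_sig_increasing: float = 0.11
    slope_sig: float = 0.02            # units/yr for intended significant increases
    slope_nonsig: float = 0.004        # units/yr for intended weak increases
    slope_dec: float = -0.004          # units/yr for the remaining (decreasing) cells
    base_level: float = 1.5
    noise_sd: float = 0.10
    cell_size: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("fraction_increasing", "fraction_sig_increasing"):
            f = getattr(self, name)
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{name}={f}: must be in [0, 1]")
        if self.fraction_sig_increasing > self.fraction_increasing:
            raise ValueError("fraction_sig_increasing must not exceed fraction_increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


LABEL_CODES = {0: "decreasing", 1: "nonsig_increasing", 2: "sig_increasing"}


def generate_trend_raster(config: SyntheticRasterConfig) -> RasterSeries:
    """Annual grids whose cells carry declared linear trends plus noise.

    A label grid records each cell's intended class (0 decreasing,
    1 weakly increasing, 2 strongly/significantly increasing); signal
    magnitudes default to values detectable at alpha = 0.05 over a
    40-year record with the default noise.
    """
    config.validate()
    rng = _rng(config.seed, "raster")
    rows, cols = config.shape
    n = rows * cols
    years = list(range(config.years[0], config.years[1] + 1))
    t = np.asarray(years, dtype=float) - config.years[0]

    n_inc = int(round(config.fraction_increasing * n))
    n_sig = int(round(config.fraction_sig_increasing * n))
    labels = np.zeros(n, dtype=int)
    order = rng.permutation(n)
    labels[order[:n_sig]] = 2
    labels[order[n_sig:n_inc]] = 1
    slopes = np.choose(labels, [config.slope_dec, config.slope_nonsig, config.slope_sig])

    stack = (config.base_level + slopes[None, :] * t[:, None])
    if config.noise_sd > 0:
        stack = stack + rng.normal(0.0, config.noise_sd, (t.size, n))
    return RasterSeries(stack.reshape(t.size, rows, cols), years,
                        cell_size=config.cell_size,
                        labels=labels.reshape(rows, cols), label_codes=dict(LABEL_CODES))


DEFAULT_CLASS_TABLE = {1: "cropland", 2: "forest", 3: "shrubland", 4: "grassland", 5: "other"}


@dataclass
class SyntheticLanduseConfig:
    shape: tuple[int, int] = (100, 100)
    years: tuple[int, int] = (1980, 2020)
    class_table: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_CLASS_TABLE))
    baseline_cropland_fraction: float = 0.4
    # year -> cumulative fraction of permanent cropland converted by that year;
    # the default mirrors a conversion programme that ramps up after 2005 and
    # plateaus after 2010.
    conversion_schedule: dict[int, float] = field(default_factory=lambda: {
        2005: 0.02, 2010: 0.18, 2015: 0.18, 2020: 0.20})
    cell_size: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.baseline_cropland_fraction <= 1.0:
            raise ValueError("baseline_cropland_fraction must be in [0, 1]")
        sched = sorted(self.conversion_schedule.items())
        fracs = [f for _, f in sched]
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ValueError("conversion fractions must be in [0, 1]")
        if any(b < a for a, b in zip(fracs, fracs[1:])):
            raise ValueError("conversion schedule must be nondecreasing in year")
        names = set(self.class_table.values())
        need = {"cropland", "forest", "shrubland", "grassland"}
        if not need <= names:
            raise ValueError(f"class table must name {sorted(need)}")


def generate_landuse_series(config: SyntheticLanduseConfig) -> LandUseSeries:
    """Annual class grids with scheduled cropland-to-vegetation conversion.

    The baseline map is constant over all pre-conversion years, so the
    permanent-cropland mask equals the baseline cropland map.  Converted
    cells switch to forest/shrubland/grassland in a fixed random order and
    never revert.
    """
    config.validate()
    rng = _rng(config.seed, "landuse")
    rows, cols = config.shape
    n = rows * cols
    years = list(range(config.years[0], config.years[1] + 1))
    inv = {name: code for code, name in config.class_table.items()}

    n_crop = int(round(config.baseline_cropland_fraction * n))
    order = rng.permutation(n)
    base = np.full(n, inv.get("other", inv["grassland"]), dtype=int)
    crop_cells = order[:n_crop]
    base[crop_cells] = inv["cropland"]
    # non-cropland background: mix of natural classes
    bg = order[n_crop:]
    base[bg] = rng.choice([inv["forest"], inv["grassland"],
                           inv.get("other", inv["grassland"])], size=bg.size)

    conv_order = rng.permutation(crop_cells)        # conversion priority, fixed
    targets = rng.choice([inv["forest"], inv["shrubland"], inv["grassland"]],
                         size=conv_order.size)
    sched = sorted(config.conversion_schedule.items())

    stack = np.empty((len(years), n), dtype=int)
    n_done = 0
    grid = base.copy()
    for i, yr in enumerate(years):
        target_frac = 0.0
        for sy, f in sched:
            if yr >= sy:
                target_frac = f
        n_target = int(round(target_frac * n_crop))
        if n_target > n_done:
            idx = conv_order[n_done:n_target]
            grid[idx] = targets[n_done:n_target]
            n_done = n_target
        stack[i] = grid
    return LandUseSeries(stack.reshape(len(years), rows, cols), years,
                         dict(config.class_table), cell_size=config.cell_size)


def generate_zones(n_units: int, shape: tuple[int, int], origin=(0.0, 0.0),
                   cell_size: float = 1.0) -> list[dict]:
    """Rectangular unit zones tiling a raster extent, as GeoJSON features.

    Synthetic stand-ins for real administrative polygons: a near-square
    tiling assigned row-major to unit ids U000, U001, ...
    """
    rows, cols = shape
    w, h = cols * cell_size, rows * cell_size
    nx = int(np.ceil(np.sqrt(n_units * w / h)))
    ny = int(np.ceil(n_units / nx))
    x0, y0 = origin
    feats = []
    k = 0
    for j in range(ny):
        for i in range(nx):
            if k >= n_units:
                break
            geom = box(x0 + i * w / nx, y0 - (j + 1) * h / ny,
                       x0 + (i + 1) * w / nx, y0 - j * h / ny)
            feats.append({"type": "Feature", "properties": {"unit_id": f"U{k:03d}"},
                          "geometry": mapping(geom)})
            k += 1
    return feats


def generate_raw_stats(n_units: int = 50, years: tuple[int, int] = (1980, 2019),
                       seed: int = 0) -> pd.DataFrame:
    """Yearbook-style raw statistics for the indicator construction stage.

    Magnitudes are loosely calibrated to prefecture-city yearbooks
    (populations of 10^5–10^7 persons, per-capita GDP growing over the
    period, grain yields of a few t/ha); they carry no spatial structure.
    """
    rng = _rng(seed, "rawstats")
    y0, y1 = years
    yrs = np.arange(y0, y1 + 1)
    rows = []
    for k in range(n_units):
        area = rng.uniform(2_000, 40_000)
        pop0 = rng.uniform(2e5, 8e6)
        growth = rng.uniform(0.002, 0.015)
        for t, yr in enumerate(yrs):
            pop = pop0 * (1 + growth) ** t
            urban_frac = min(0.9, rng.uniform(0.15, 0.3) + 0.01 * t)
            employed = pop * rng.uniform(0.45, 0.65)
            gdp_pc = rng.uniform(1_000, 4_000) * (1.08) ** t
            gdp = gdp_pc * pop
            sec_share = rng.uniform(0.3, 0.5)
            ter_share = rng.uniform(0.2, 0.45)
            prim = gdp * max(0.05, 1 - sec_share - ter_share)
            sown = area * rng.uniform(8, 40)        # ha
            rows.append({
                "unit_id": f"U{k:03d}", "year": int(yr), "area_km2": area,
                "population_total": pop, "population_urban": pop * urban_frac,
                "population_rural": pop * (1 - urban_frac),
                "population_employed": employed,
                "gdp": gdp, "gdp_primary": prim, "gdp_secondary": gdp * sec_share,
                "gdp_tertiary": gdp * ter_share,
                "grain_output_kg": sown * rng.uniform(1_600, 9_000),
                "sown_grain_area_ha": sown,
                "urban_income": gdp_pc * rng.uniform(0.8, 1.2),
                "rural_income": gdp_pc * rng.uniform(0.25, 0.5),
                "fiscal_revenue": gdp * rng.uniform(0.05, 0.12),
                "fiscal_expenditure": gdp * rng.uniform(0.06, 0.15),
                "retail_sales": gdp * rng.uniform(0.25, 0.45),
                "fixed_asset_investment": gdp * rng.uniform(1.1, 2.8),
            })
    return pd.DataFrame(rows)
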
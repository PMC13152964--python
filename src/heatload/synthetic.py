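"""Miniature synthetic climate archive with analytically known structure.

Emulates the layout of a daily downscaled multi-model climate archive —
several models x scenarios x four variables of daily gridded values — at a
desk scale that runs in seconds, so every pipeline stage can be exercised
without downloading real data.

Each variable follows a deterministic signal plus AR(1) weather noise:

    value(lat, lon, doy, year) = mean(lat, lon)
                               + amplitude * cos(2*pi*(doy - peak(lat)) / n_days)
                               + trend(year)              (air temperature only)
                               + model offset             (air temperature only)
                               + AR(1) noise

The seasonal peak day flips by half a year across the equator (hemisphere
phase flip) and the trend is a per-scenario warming rate in deg C per decade
relative to the baseline midpoint.  Files are written with raw (unclamped)
noisy values plus injected sentinel and missing entries, so the pipeline's
quality control is genuinely exercised; the closed-form truth is the
noise-free signal clamped to physical ranges, evaluated here with plain
month-length tables — no NetCDF, no calendar library — so pipeline and truth
are independent code paths.

The generator also writes a toy land mask (an eastern "ocean" strip) and two
rectangular toy "countries" as GeoJSON.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import xarray as xr

from .climate_io import DailyClimateField, GridSpec, LandMask, VARIABLES, write_daily_field
from .exposure import RegionGrid, build_summary, cell_areas, rasterize_regions
from .hli import CategoryGrid, HliCoefficients, DEFAULT_COEFFICIENTS, classify_hli, \
    compute_bgt, compute_hli
from .seasonal import Period, SEASONS, Season

__all__ = [
    "VariableModel", "SyntheticConfig", "SyntheticTruth",
    "generate_archive", "expected_summary",
    "make_toy_land_mask", "make_toy_regions",
]

MONTH_LENGTHS = {
    "noleap": (31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31),
    "360_day": (30,) * 12,
}

#: physical clamping ranges applied by QC; the truth applies the same ranges
_CLAMP = {
    "air_temperature": (-90.0, 60.0),   # deg C; never active at defaults
    "relative_humidity": (0.0, 100.0),
    "shortwave_radiation": (0.0, np.inf),
    "wind_speed": (0.0, np.inf),
}


@dataclass(frozen=True)
class VariableModel:
    """Deterministic signal + noise parameters for one climate variable.

    ``mean0`` is the value at the grid's central longitude on the equator;
    ``lat_gradient`` (per degree of |latitude|) and ``lon_gradient`` (per
    degree of longitude from the grid center) tilt the mean field;
    ``amplitude`` scales the seasonal cosine; ``noise_sd`` is the stationary
    daily standard deviation of the AR(1) noise with coefficient ``ar1``.
    """

    mean0: float
    lat_gradient: float = 0.0
    lon_gradient: float = 0.0
    amplitude: float = 0.0
    noise_sd: float = 0.0
    ar1: float = 0.0


def _default_variables() -> dict:
    # units: deg C (converted to K on disk), %, W/m^2, m/s
    return {
        "air_temperature": VariableModel(35.0, -1.2, 3.2, 5.0, 2.0, 0.6),
        "relative_humidity": VariableModel(55.0, 0.0, -1.5, -10.0, 6.0, 0.5),
        "shortwave_radiation": VariableModel(220.0, -4.0, 0.0, 60.0, 30.0, 0.4),
        "wind_speed": VariableModel(3.0, 0.0, 0.0, 0.8, 0.8, 0.3),
    }


def _default_periods() -> list[Period]:
    # 3-year mini-periods standing in for the 30/25-year study windows
    return [Period("CliNo", 1985, 1987), Period("early", 2040, 2042),
            Period("late", 2095, 2097)]


@dataclass(frozen=True)
class SyntheticConfig:
    """Complete description of a synthetic archive; truth derives from it only."""

    nlat: int = 8
    nlon: int = 16
    lat0: float = -0.375           # grid straddles the equator, biased north
    lon0: float = 10.0
    step: float = 0.25
    model_ids: tuple = ("modA", "modB", "modC")
    calendars: tuple = ("noleap", "noleap", "360_day")
    scenarios: dict = field(default_factory=lambda: {"ssp_low": 0.15, "ssp_high": 0.75})
    periods: tuple = field(default_factory=lambda: tuple(_default_periods()))
    variables: dict = field(default_factory=_default_variables)
    peak_frac: float = 197.0 / 365.0   # NH seasonal peak as fraction of the year
    temp_model_spread: float = 0.4     # deg C between adjacent model offsets
    missing_rate: float = 0.002
    sentinel_rate: float = 0.002
    seed: int = 0

    def __post_init__(self):
        if len(self.calendars) != len(self.model_ids):
            raise ValueError("one calendar per model required")
        for cal in self.calendars:
            if cal not in MONTH_LENGTHS:
                raise ValueError(f"unsupported calendar {cal!r}")
        for vm in self.variables.values():
            if vm.noise_sd < 0 or not (0 <= vm.ar1 < 1):
                raise ValueError("noise_sd must be >= 0 and ar1 in [0, 1)")
        for rate in (self.missing_rate, self.sentinel_rate):
            if not 0 <= rate <= 1:
                raise ValueError("injection rates must be in [0, 1]")

    @property
    def grid(self) -> GridSpec:
        return GridSpec.regular(self.nlat, self.nlon, self.lat0, self.lon0, self.step)

    @property
    def baseline(self) -> Period:
        return self.periods[0]

    @property
    def trend_ref_year(self) -> float:
        p = self.baseline
        return (p.start_year + p.end_year) / 2.0

    def model_offset(self, model_id: str, variable: str) -> float:
        if variable != "air_temperature":
            return 0.0
        i = self.model_ids.index(model_id)
        return (i - (len(self.model_ids) - 1) / 2.0) * self.temp_model_spread

    def calendar_of(self, model_id: str) -> str:
        return self.calendars[self.model_ids.index(model_id)]


# ---------------------------------------------------------------------------
# deterministic signal (shared by generator and truth)
# ---------------------------------------------------------------------------


def _deterministic_day(cfg: SyntheticConfig, variable: str, model_id: str,
                       rate: float, year: int, doy: int, n_days: int) -> np.ndarray:
    """Noise-free daily field (nlat, nlon) in natural units (temperature deg C)."""
    vm = cfg.variables[variable]
    grid = cfg.grid
    lat = grid.lat[:, None]
    lon = grid.lon[None, :]
    lon_c = float(grid.lon.mean())
    mean = vm.mean0 + vm.lat_gradient * np.abs(lat) + vm.lon_gradient * (lon - lon_c)
    peak_nh = cfg.peak_frac * n_days
    peak = np.where(lat >= 0, peak_nh, (peak_nh + n_days / 2.0) % n_days)
    seasonal = vm.amplitude * np.cos(2 * np.pi * (doy - peak) / n_days)
    out = mean + seasonal + np.zeros((grid.lat.size, grid.lon.size))
    if variable == "air_temperature":
        out = out + rate * (year - cfg.trend_ref_year) / 10.0
        out = out + cfg.model_offset(model_id, variable)
    return out


def _year_days(calendar: str):
    lengths = MONTH_LENGTHS[calendar]
    months = np.repeat(np.arange(1, 13), lengths)
    doys = np.arange(1, sum(lengths) + 1)
    return months, doys


# ---------------------------------------------------------------------------
# truth (no daily data files involved)
# ---------------------------------------------------------------------------


@dataclass
class SyntheticTruth:
    """Closed-form expectations implied by a SyntheticConfig."""

    config: SyntheticConfig

    def seasonal_mean(self, model_id: str, scenario_id: str, variable: str,
                      period: Period, season: Season) -> np.ndarray:
        """Expected seasonal-mean field for one model (temperature in deg C)."""
        cfg = self.config
        rate = 0.0 if scenario_id == "historical" else cfg.scenarios[scenario_id]
        cal = cfg.calendar_of(model_id)
        months, doys = _year_days(cal)
        n_days = doys.size
        sel = np.isin(months, list(season.months))
        lo, hi = _CLAMP[variable]
        acc = np.zeros(cfg.grid.shape)
        count = 0
        for year in range(period.start_year, period.end_year + 1):
            for doy in doys[sel]:
                day = _deterministic_day(cfg, variable, model_id, rate,
                                         year, int(doy), n_days)
                acc += np.clip(day, lo, hi)
                count += 1
        return acc / count

    def ensemble_mean(self, scenario_id: str, variable: str,
                      period: Period, season: Season) -> np.ndarray:
        cfg = self.config
        stack = [self.seasonal_mean(m, scenario_id, variable, period, season)
                 for m in cfg.model_ids]
        return np.mean(stack, axis=0)

    def mean_noise_sd(self, model_id: str, variable: str,
                      period: Period, season: Season) -> float:
        """Std dev of one model's seasonal-mean noise (same for every cell).

        AR(1) autocorrelation inflates the variance of the mean of n days by
        approximately (1 + rho) / (1 - rho).
        """
        cfg = self.config
        vm = cfg.variables[variable]
        if vm.noise_sd == 0:
            return 0.0
        months, _ = _year_days(cfg.calendar_of(model_id))
        n = int(np.isin(months, list(season.months)).sum()) \
            * (period.end_year - period.start_year + 1)
        inflation = (1.0 + vm.ar1) / (1.0 - vm.ar1)
        return float(vm.noise_sd * np.sqrt(inflation / n))

    def ensemble_noise_sd(self, variable: str, period: Period, season: Season) -> float:
        """Std dev of the noise on the equal-weighted ensemble seasonal mean."""
        sds = [self.mean_noise_sd(m, variable, period, season)
               for m in self.config.model_ids]
        return float(np.sqrt(np.sum(np.square(sds))) / len(sds))

    def hli_mean_sd(self, scenario_id: str, period: Period, season: Season,
                    coefficients: HliCoefficients = DEFAULT_COEFFICIENTS) -> np.ndarray:
        """Per-cell delta-method sd of the ensemble seasonal-mean HLI.

        Propagates each variable's seasonal-mean noise sd through the BGT and
        HLI formulas linearised at the expected values (branch fixed by the
        expected BGT; the branch discontinuity itself is not modelled).
        """
        ta = self.ensemble_mean(scenario_id, "air_temperature", period, season)
        rh = self.ensemble_mean(scenario_id, "relative_humidity", period, season)
        sr = self.ensemble_mean(scenario_id, "shortwave_radiation", period, season)
        ws = self.ensemble_mean(scenario_id, "wind_speed", period, season)
        bgt = compute_bgt(ta, sr, coefficients)
        a, b, c, _ = coefficients.bgt
        dbgt_dta = a + b / (2.0 * np.sqrt(np.maximum(ta, 1e-6)))
        dbgt_dsr = c / ((sr + 1.0) * np.log(10.0))
        upper = bgt >= coefficients.branch_bgt
        g = np.where(upper, coefficients.high[2], coefficients.low[2])
        r = np.where(upper, coefficients.high[1], coefficients.low[1])
        dws = np.where(upper,
                       coefficients.high[3] - np.exp(coefficients.high_exp - ws),
                       coefficients.low[3])
        s = {v: self.ensemble_noise_sd(v, period, season)
             for v in self.config.variables}
        var = ((g * dbgt_dta * s["air_temperature"]) ** 2
               + (g * dbgt_dsr * s["shortwave_radiation"]) ** 2
               + (r * s["relative_humidity"]) ** 2
               + (dws * s["wind_speed"]) ** 2)
        return np.sqrt(var)

    def share_envelope(self, mask: LandMask, regions: RegionGrid | None = None,
                       k: float = 5.0,
                       coefficients: HliCoefficients = DEFAULT_COEFFICIENTS) -> pd.DataFrame:
        """Max plausible Extreme-share deviation (%) per summary row.

        A cell's Extreme flag can differ from its expectation only when the
        expected ensemble HLI lies within ``k`` noise-sd of the Extreme
        threshold; the envelope for a row is the area share of such
        borderline cells within the row's region.  Rows align with
        ``expected_summary``; the column is ``share_envelope_pct``.
        """
        cfg = self.config
        areas = cell_areas(cfg.grid)
        thr = coefficients.thresholds[-1]
        region_list = [("GLOBAL", "Global", None)]
        if regions is not None:
            for rid in sorted(regions.names):
                region_list.append((rid, regions.names[rid],
                                    regions.region_id == rid))
        period_by_label = {p.label: p for p in cfg.periods}
        combos = [("historical", cfg.baseline.label)] + [
            (sc, p.label) for p in cfg.periods[1:] for sc in sorted(cfg.scenarios)]
        rows = []
        for scenario_id, plabel in combos:
            period = period_by_label[plabel]
            for slabel, season in SEASONS.items():
                ta = self.ensemble_mean(scenario_id, "air_temperature", period, season)
                rh = self.ensemble_mean(scenario_id, "relative_humidity", period, season)
                sr = self.ensemble_mean(scenario_id, "shortwave_radiation", period, season)
                ws = self.ensemble_mean(scenario_id, "wind_speed", period, season)
                hli = compute_hli(compute_bgt(ta, sr, coefficients), rh, ws,
                                  coefficients)
                sd = self.hli_mean_sd(scenario_id, period, season, coefficients)
                borderline = np.abs(hli - thr) < k * sd
                for rid, rname, selector in region_list:
                    land = mask.is_land if selector is None else mask.is_land & selector
                    denom = areas[land].sum()
                    env = (100.0 * areas[land & borderline].sum() / denom
                           if denom > 0 else np.nan)
                    rows.append({"region_id": rid, "region_name": rname,
                                 "season": slabel, "period": plabel,
                                 "scenario": ("historical" if scenario_id == "historical"
                                              else scenario_id),
                                 "share_envelope_pct": env})
        return pd.DataFrame(rows)

    def category_grid(self, scenario_id: str, period: Period, season: Season,
                      coefficients: HliCoefficients = DEFAULT_COEFFICIENTS,
                      mask: LandMask | None = None) -> CategoryGrid:
        """Expected welfare categories from the ensemble-mean climate."""
        cfg = self.config
        ta = self.ensemble_mean(scenario_id, "air_temperature", period, season)
        rh = self.ensemble_mean(scenario_id, "relative_humidity", period, season)
        sr = self.ensemble_mean(scenario_id, "shortwave_radiation", period, season)
        ws = self.ensemble_mean(scenario_id, "wind_speed", period, season)
        hli = compute_hli(compute_bgt(ta, sr, coefficients), rh, ws, coefficients)
        codes = classify_hli(hli, coefficients.thresholds)
        codes = np.where((ta < 0) & (codes == -1), 0, codes).astype(np.int8)
        if mask is not None:
            codes = np.where(mask.is_land, codes, -1).astype(np.int8)
        coords = {"lat": cfg.grid.lat, "lon": cfg.grid.lon}
        return CategoryGrid(grid=cfg.grid, season=season.label, period=period.label,
                            scenario_id=scenario_id,
                            codes=xr.DataArray(codes, dims=("lat", "lon"),
                                               coords=coords))


def expected_summary(truth: SyntheticTruth, mask: LandMask,
                     regions: RegionGrid | None = None,
                     coefficients: HliCoefficients = DEFAULT_COEFFICIENTS) -> pd.DataFrame:
    """Analytic Extreme-share table implied by the generator configuration.

    Computed from the closed-form expectations only — no daily data — in the
    same row layout as the pipeline's summary, for end-to-end comparison.
    """
    cfg = truth.config
    areas = cell_areas(cfg.grid)
    seasons = tuple(SEASONS)
    proj_periods = tuple(p.label for p in cfg.periods[1:])
    scenarios = tuple(cfg.scenarios)
    period_by_label = {p.label: p for p in cfg.periods}
    baseline_grids = {s: truth.category_grid("historical", cfg.baseline,
                                             SEASONS[s], coefficients, mask)
                      for s in seasons}
    grids = {(s, p, sc): truth.category_grid(sc, period_by_label[p],
                                             SEASONS[s], coefficients, mask)
             for s in seasons for p in proj_periods for sc in scenarios}
    return build_summary(grids, baseline_grids, areas, mask, regions,
                         seasons=seasons, periods=proj_periods,
                         scenarios=scenarios, baseline_label=cfg.baseline.label)


# ---------------------------------------------------------------------------
# toy geography
# ---------------------------------------------------------------------------


def make_toy_land_mask(grid: GridSpec, ocean_cols: int | None = None) -> LandMask:
    """Land everywhere except an eastern ocean strip (~1/4 of the columns)."""
    if ocean_cols is None:
        ocean_cols = max(1, grid.lon.size // 4)
    is_land = np.ones(grid.shape, dtype=bool)
    if ocean_cols:
        is_land[:, -ocean_cols:] = False
    return LandMask(grid=grid, is_land=is_land)


def make_toy_regions(grid: GridSpec) -> dict:
    """Two rectangular countries over the western land cells, as GeoJSON."""
    from shapely.geometry import box, mapping

    half_lat = grid.lat_step / 2
    half_lon = grid.lon_step / 2
    n_a = max(1, grid.lon.size // 3)
    n_b = max(1, grid.lon.size // 4)
    west = grid.lon[0] - half_lon
    split = grid.lon[n_a - 1] + half_lon
    east = grid.lon[n_a + n_b - 1] + half_lon
    south, north = grid.lat[0] - half_lat, grid.lat[-1] + half_lat
    feats = []
    for rid, name, (x0, x1) in [(1, "Westland", (west, split)),
                                (2, "Eastmark", (split, east))]:
        feats.append({"type": "Feature",
                      "properties": {"region_id": rid, "name": name},
                      "geometry": mapping(box(x0, south, x1, north))})
    return {"type": "FeatureCollection", "features": feats}


# ---------------------------------------------------------------------------
# archive generation
# ---------------------------------------------------------------------------


def _time_axis(start_year: int, end_year: int, calendar: str):
    end_day = 30 if calendar == "360_day" else 31
    try:
        return xr.date_range(start=f"{start_year}-01-01",
                             end=f"{end_year}-12-{end_day}",
                             freq="D", calendar=calendar, use_cftime=True)
    except TypeError:  # older xarray signature
        return xr.cftime_range(start=f"{start_year}-01-01",
                               end=f"{end_year}-12-{end_day}",
                               freq="D", calendar=calendar)


def _simulate(cfg: SyntheticConfig, model_id: str, scenario_id: str,
              variable: str, period: Period) -> DailyClimateField:
    """Daily values for one model/scenario/variable over one period's years."""
    rate = 0.0 if scenario_id == "historical" else cfg.scenarios[scenario_id]
    cal = cfg.calendar_of(model_id)
    months, doys = _year_days(cal)
    n_days = doys.size
    years = np.arange(period.start_year, period.end_year + 1)
    vm = cfg.variables[variable]
    grid = cfg.grid
    lat = grid.lat[:, None]
    lon = grid.lon[None, :]
    lon_c = float(grid.lon.mean())
    mean = vm.mean0 + vm.lat_gradient * np.abs(lat) + vm.lon_gradient * (lon - lon_c)
    peak_nh = cfg.peak_frac * n_days
    peak = np.where(lat >= 0, peak_nh, (peak_nh + n_days / 2.0) % n_days)
    doy_all = np.tile(doys, years.size)[:, None, None]
    year_all = np.repeat(years, n_days).astype(float)
    det = mean[None] + vm.amplitude * np.cos(
        2 * np.pi * (doy_all - peak[None]) / n_days)
    det = det + np.zeros((doy_all.size, grid.lat.size, grid.lon.size))
    if variable == "air_temperature":
        det += (rate * (year_all - cfg.trend_ref_year) / 10.0)[:, None, None]
        det += cfg.model_offset(model_id, variable)

    im = cfg.model_ids.index(model_id)
    isc = (["historical"] + sorted(cfg.scenarios)).index(scenario_id)
    iv = sorted(VARIABLES).index(variable)
    rng = np.random.default_rng([cfg.seed, im, isc, iv, period.start_year])
    vals = det
    if vm.noise_sd > 0:
        # AR(1) in time, independent across cells, stationary sd = noise_sd
        n_t = det.shape[0]
        eps = rng.standard_normal(det.shape)
        noise = np.empty_like(eps)
        noise[0] = eps[0]
        innov = np.sqrt(1.0 - vm.ar1 ** 2)
        for t in range(1, n_t):
            noise[t] = vm.ar1 * noise[t - 1] + innov * eps[t]
        vals = det + vm.noise_sd * noise
    vals = np.array(vals, dtype="float64", copy=True)
    if cfg.missing_rate > 0:
        miss = rng.random(vals.shape) < cfg.missing_rate
        vals[miss] = np.nan
    if cfg.sentinel_rate > 0:
        sent = rng.random(vals.shape) < cfg.sentinel_rate
        vals[sent] = 1e20
    if variable == "air_temperature":
        vals = vals + 273.15  # archive stores kelvin

    time = _time_axis(period.start_year, period.end_year, cal)
    da = xr.DataArray(vals, dims=("time", "lat", "lon"),
                      coords={"time": time, "lat": cfg.grid.lat, "lon": cfg.grid.lon})
    return DailyClimateField(variable=variable, data=da, model_id=model_id,
                             scenario_id=scenario_id, units=VARIABLES[variable])


def generate_archive(config: SyntheticConfig, out: str) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Write the full synthetic archive under ``out`` and return its manifest.

    Layout: ``<out>/<model>/<scenario>/<variable>_<y0>-<y1>.nc`` plus
    ``land_mask.nc``, ``regions.geojson`` and ``manifest.csv``.  The baseline
    period is written under scenario ``historical``; projection periods under
    each configured scenario.  Identical config (incl. seed) gives
    byte-identical values.
    """
    os.makedirs(out, exist_ok=True)
    rows = []
    for model_id in config.model_ids:
        for period in config.periods:
            scen_ids = (["historical"] if period is config.baseline
                        else sorted(config.scenarios))
            for scenario_id in scen_ids:
                d = os.path.join(out, model_id, scenario_id)
                os.makedirs(d, exist_ok=True)
                for variable in sorted(VARIABLES):
                    f = _simulate(config, model_id, scenario_id, variable, period)
                    path = os.path.join(
                        d, f"{variable}_{period.start_year}-{period.end_year}.nc")
                    write_daily_field(f, path)
                    rows.append({"model": model_id, "scenario": scenario_id,
                                 "variable": variable, "period": period.label,
                                 "start_year": period.start_year,
                                 "end_year": period.end_year,
                                 "calendar": config.calendar_of(model_id),
                                 "path": os.path.relpath(path, out)})
    mask = make_toy_land_mask(config.grid)
    mask_path = os.path.join(out, "land_mask.nc")
    xr.Dataset({"is_land": xr.DataArray(mask.is_land.astype("i1"),
                                        dims=("lat", "lon"),
                                        coords={"lat": config.grid.lat,
                                                "lon": config.grid.lon})}
               ).to_netcdf(mask_path)
    import json
    with open(os.path.join(out, "regions.geojson"), "w") as fh:
        json.dump(make_toy_regions(config.grid), fh)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(out, "manifest.csv"), index=False)
    return manifest, SyntheticTruth(config=config)
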
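"""Heat-Load Index (HLI) for beef cattle: black-globe temperature estimation,
the two-branch HLI formula, and thermal-welfare classification.

The HLI combines black-globe temperature (BGT, deg C), relative humidity
(RH, %) and wind speed (WS, m/s) into a single heat-stress number.  BGT is
not a GCM output, so it is first estimated empirically from air temperature
Ta (deg C) and downwelling shortwave radiation SR (W/m^2):

    BGT = 1.33*Ta - 2.65*sqrt(Ta) + 3.21*log10(SR + 1) + 3.5

The HLI itself is a two-branch formula with the branch switched on BGT:

    BGT <  25:  HLI = 10.66 + 0.28*RH + 1.3*BGT - WS
    BGT >= 25:  HLI =  8.62 + 0.38*RH + 1.55*BGT - 0.5*WS + exp(2.4 - WS)

Seasonal-mean HLI values are classified into five thermal-welfare categories
calibrated on feedlot panting-score studies:

    Comfort  HLI <= 70       Mild    70 < HLI <= 77
    Moderate 77 < HLI <= 86  Severe  86 < HLI <= 96   Extreme  HLI > 96

All coefficients and thresholds live in ``HliCoefficients`` so an alternative
published calibration can be swapped in without touching code.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import xarray as xr

from .climate_io import GridSpec
from .seasonal import SeasonalClimatology

__all__ = [
    "HLI_THRESHOLDS", "CATEGORY_NAMES", "MISSING_CATEGORY",
    "HliCoefficients", "DEFAULT_COEFFICIENTS", "ClassificationError",
    "WelfareCategory", "HliField", "CategoryGrid",
    "compute_bgt", "compute_hli", "classify_hli", "category_name",
    "hli_from_climatology",
]

#: upper bounds of Comfort, Mild, Moderate, Severe (Extreme is unbounded)
HLI_THRESHOLDS: tuple[float, ...] = (70.0, 77.0, 86.0, 96.0)
CATEGORY_NAMES: tuple[str, ...] = ("Comfort", "Mild", "Moderate", "Severe", "Extreme")
#: integer code marking a cell with no classification (ocean / missing input)
MISSING_CATEGORY: int = -1


class ClassificationError(ValueError):
    """A non-finite value was passed where a finite HLI is required."""


@dataclass(frozen=True)
class HliCoefficients:
    """Editable coefficient table for the BGT and HLI formulas."""

    # BGT = a*Ta + b*sqrt(Ta) + c*log10(SR + 1) + d
    bgt: tuple[float, float, float, float] = (1.33, -2.65, 3.21, 3.5)
    # lower branch (BGT < branch_bgt): i + rh*RH + g*BGT + w*WS
    low: tuple[float, float, float, float] = (10.66, 0.28, 1.3, -1.0)
    # upper branch: i + rh*RH + g*BGT + w*WS + exp(e - WS)
    high: tuple[float, float, float, float] = (8.62, 0.38, 1.55, -0.5)
    high_exp: float = 2.4
    branch_bgt: float = 25.0  # upper branch applies at BGT >= branch_bgt
    thresholds: tuple[float, ...] = HLI_THRESHOLDS


DEFAULT_COEFFICIENTS = HliCoefficients()


@dataclass(frozen=True)
class WelfareCategory:
    """One thermal-welfare band: integer code, name and half-open HLI bounds."""

    code: int
    name: str
    lower: float  # exclusive
    upper: float  # inclusive


def _categories(thresholds=HLI_THRESHOLDS) -> tuple[WelfareCategory, ...]:
    edges = (-np.inf,) + tuple(thresholds) + (np.inf,)
    return tuple(WelfareCategory(i, CATEGORY_NAMES[i], edges[i], edges[i + 1])
                 for i in range(len(CATEGORY_NAMES)))


WELFARE_CATEGORIES = _categories()


def compute_bgt(air_temperature, shortwave_radiation,
                coefficients: HliCoefficients = DEFAULT_COEFFICIENTS):
    """Black-globe temperature (deg C) from air temperature and radiation.

    ``air_temperature`` is in deg C, ``shortwave_radiation`` in W/m^2.  The
    sqrt term restricts the formula to Ta >= 0 deg C; sub-zero inputs yield
    missing (NaN) rather than an extrapolated value.  At SR = 0 the radiation
    term is exactly zero.
    """
    ta = np.asarray(air_temperature, dtype=float)
    sr = np.asarray(shortwave_radiation, dtype=float)
    a, b, c, d = coefficients.bgt
    valid = ta >= 0
    ta_safe = np.where(valid, ta, 0.0)
    out = a * ta_safe + b * np.sqrt(ta_safe) + c * np.log10(sr + 1.0) + d
    out = np.where(valid, out, np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def compute_hli(bgt, relative_humidity, wind_speed,
                coefficients: HliCoefficients = DEFAULT_COEFFICIENTS):
    """Heat-Load Index from black-globe temperature, humidity and wind.

    The two linear branches switch at ``coefficients.branch_bgt`` (upper
    branch applies at equality).  Missing inputs propagate to missing output.
    """
    bgt = np.asarray(bgt, dtype=float)
    rh = np.asarray(relative_humidity, dtype=float)
    ws = np.asarray(wind_speed, dtype=float)
    il, rl, gl, wl = coefficients.low
    ih, rhc, gh, wh = coefficients.high
    low = il + rl * rh + gl * bgt + wl * ws
    high = ih + rhc * rh + gh * bgt + wh * ws + np.exp(coefficients.high_exp - ws)
    out = np.where(bgt >= coefficients.branch_bgt, high, low)
    out = np.where(np.isfinite(bgt) & np.isfinite(rh) & np.isfinite(ws), out, np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def classify_hli(hli, thresholds=HLI_THRESHOLDS):
    """Classify HLI value(s) into welfare-category codes 0..4.

    Threshold values belong to the lower category (Comfort at exactly 70,
    Mild at exactly 77, ...).  A non-finite scalar raises
    ``ClassificationError``; in arrays, non-finite entries become
    ``MISSING_CATEGORY`` (-1).
    """
    thr = np.asarray(thresholds, dtype=float)
    arr = np.asarray(hli, dtype=float)
    if arr.ndim == 0:
        if not np.isfinite(arr):
            raise ClassificationError(f"cannot classify non-finite HLI value {hli!r}")
        return int(np.searchsorted(thr, float(arr), side="left"))
    codes = np.searchsorted(thr, np.where(np.isfinite(arr), arr, 0.0),
                            side="left").astype(np.int8)
    codes[~np.isfinite(arr)] = MISSING_CATEGORY
    return codes


def category_name(code: int) -> str:
    """Human-readable name for a category code (-1 -> 'missing')."""
    if code == MISSING_CATEGORY:
        return "missing"
    return CATEGORY_NAMES[code]


@dataclass
class HliField:
    """Per-cell seasonal-mean BGT and HLI with provenance labels."""

    grid: GridSpec
    season: str
    period: str
    scenario_id: str
    bgt: xr.DataArray
    hli: xr.DataArray


@dataclass
class CategoryGrid:
    """Per-cell welfare-category codes (0..4; -1 where unclassified)."""

    grid: GridSpec
    season: str
    period: str
    scenario_id: str
    codes: xr.DataArray


def hli_from_climatology(clim: SeasonalClimatology,
                         coefficients: HliCoefficients = DEFAULT_COEFFICIENTS,
                         subzero: str = "comfort") -> tuple[HliField, CategoryGrid]:
    """Chain BGT -> HLI -> category over an ensemble seasonal climatology.

    The climatology must carry all four variables; air temperature in kelvin
    is converted to deg C (values above 150 are taken to be kelvin).

    Cells whose seasonal-mean air temperature is below 0 deg C fall outside
    the BGT formula's domain.  With ``subzero="comfort"`` (default) they are
    assigned the Comfort category directly — at such temperatures the index
    cannot approach the first threshold — with BGT and HLI recorded missing;
    with ``subzero="missing"`` they are left unclassified.
    """
    required = ("air_temperature", "relative_humidity",
                "shortwave_radiation", "wind_speed")
    missing = [v for v in required if v not in clim.means]
    if missing:
        raise ValueError(f"climatology lacks variable(s): {missing}")
    if subzero not in ("comfort", "missing"):
        raise ValueError("subzero must be 'comfort' or 'missing'")
    ta = np.asarray(clim.means["air_temperature"], dtype=float)
    finite_ta = ta[np.isfinite(ta)]
    # kelvin -> deg C if values are clearly on the kelvin scale
    if finite_ta.size and finite_ta.max() > 150.0:
        ta = ta - 273.15
    rh = np.asarray(clim.means["relative_humidity"], dtype=float)
    sr = np.asarray(clim.means["shortwave_radiation"], dtype=float)
    ws = np.asarray(clim.means["wind_speed"], dtype=float)

    bgt = compute_bgt(ta, sr, coefficients)
    hli = compute_hli(bgt, rh, ws, coefficients)
    codes = classify_hli(hli, coefficients.thresholds)
    if subzero == "comfort":
        subzero_cells = np.isfinite(ta) & (ta < 0.0) & np.isfinite(rh) \
            & np.isfinite(sr) & np.isfinite(ws)
        codes = np.where(subzero_cells, 0, codes).astype(np.int8)

    coords = {"lat": clim.grid.lat, "lon": clim.grid.lon}
    dims = ("lat", "lon")
    field = HliField(grid=clim.grid, season=clim.season.label,
                     period=clim.period.label, scenario_id=clim.scenario_id,
                     bgt=xr.DataArray(bgt, dims=dims, coords=coords),
                     hli=xr.DataArray(hli, dims=dims, coords=coords))
    cats = CategoryGrid(grid=clim.grid, season=clim.season.label,
                        period=clim.period.label, scenario_id=clim.scenario_id,
                        codes=xr.DataArray(codes, dims=dims, coords=coords))
    return field, cats
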
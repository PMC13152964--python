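"""Reading, quality control and land-masking of daily gridded climate fields.

The pipeline consumes one variable per file set in CF-convention NetCDF with
dimensions ``(time, lat, lon)``.  Four variables are recognised, matching the
daily output of bias-corrected downscaled GCM archives:

========================  =========  ==============================
variable                  units      QC rule
========================  =========  ==============================
``air_temperature``       K          values <= 0 K -> missing
``relative_humidity``     %          clamped into [0, 100]
``shortwave_radiation``   W/m^2      negative -> 0
``wind_speed``            m/s        negative -> 0
========================  =========  ==============================

In addition, for every variable, sentinel placeholders (|value| >= 1e19,
guarding the common ``1e+20`` missing-data marker against single-precision
round-off) are replaced by missing before the variable-specific rule is
applied.  ``qc_clean`` is idempotent.
"""

from __future__ import annotations

import glob
import os
from dataclasses import dataclass, field as dc_field, replace

import numpy as np
import xarray as xr

__all__ = [
    "VARIABLES",
    "SENTINEL_THRESHOLD",
    "GridSpec",
    "DailyClimateField",
    "LandMask",
    "FormatError",
    "GridMismatchError",
    "ConfigurationError",
    "read_daily_fields",
    "write_daily_field",
    "qc_clean",
    "apply_land_mask",
]

#: canonical variable registry: name -> expected units string
VARIABLES = {
    "air_temperature": "K",
    "relative_humidity": "%",
    "shortwave_radiation": "W m-2",
    "wind_speed": "m s-1",
}

#: magnitude at or above which a value is treated as the 1e+20 missing sentinel
SENTINEL_THRESHOLD = 1e19


class FormatError(ValueError):
    """A file does not declare the expected variable, units or coordinates."""


class GridMismatchError(ValueError):
    """Two gridded objects do not share the same lat/lon coordinates."""


class ConfigurationError(ValueError):
    """An operation was asked to handle an unknown variable or option."""


# ---------------------------------------------------------------------------
# grid description
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GridSpec:
    """A regular lat-lon grid of cell centers.

    Parameters
    ----------
    lat : ndarray
        Cell-center latitudes in degrees north, strictly ascending, regular.
    lon : ndarray
        Cell-center longitudes in degrees east, strictly ascending, regular.
    """

    lat: np.ndarray
    lon: np.ndarray

    def __post_init__(self):
        lat = np.asarray(self.lat, dtype=float)
        lon = np.asarray(self.lon, dtype=float)
        object.__setattr__(self, "lat", lat)
        object.__setattr__(self, "lon", lon)
        for name, c in (("lat", lat), ("lon", lon)):
            if c.ndim != 1 or c.size < 1:
                raise ValueError(f"{name} centers must be a 1-D array")
            if c.size > 1:
                steps = np.diff(c)
                if np.any(steps <= 0):
                    raise ValueError(f"{name} centers must be strictly ascending")
                if not np.allclose(steps, steps[0], rtol=0, atol=1e-8):
                    raise ValueError(f"{name} centers must be regularly spaced")
        if lat[0] - self.lat_step / 2 < -90 - 1e-9 or lat[-1] + self.lat_step / 2 > 90 + 1e-9:
            raise ValueError("latitude cell bounds must lie within [-90, 90]")

    @property
    def lat_step(self) -> float:
        return float(self.lat[1] - self.lat[0]) if self.lat.size > 1 else 0.25

    @property
    def lon_step(self) -> float:
        return float(self.lon[1] - self.lon[0]) if self.lon.size > 1 else 0.25

    @property
    def shape(self) -> tuple[int, int]:
        return (self.lat.size, self.lon.size)

    def lat_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Lower and upper latitude edge of every grid row."""
        half = self.lat_step / 2
        return self.lat - half, self.lat + half

    @classmethod
    def regular(cls, nlat: int, nlon: int, lat0: float, lon0: float,
                step: float = 0.25) -> "GridSpec":
        """Build an ``nlat x nlon`` grid with the given south-west center."""
        return cls(lat0 + step * np.arange(nlat), lon0 + step * np.arange(nlon))

    @classmethod
    def from_dataset(cls, ds: xr.Dataset | xr.DataArray) -> "GridSpec":
        return cls(np.asarray(ds["lat"]), np.asarray(ds["lon"]))

    def matches(self, other: "GridSpec", atol: float = 1e-8) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.lat, other.lat, atol=atol)
            and np.allclose(self.lon, other.lon, atol=atol)
        )


def _require_same_grid(a: GridSpec, b: GridSpec, what: str) -> None:
    if not a.matches(b):
        raise GridMismatchError(f"lat/lon grids differ: {what}")


# ---------------------------------------------------------------------------
# daily field container
# ---------------------------------------------------------------------------


@dataclass
class DailyClimateField:
    """One variable's daily values on a regular grid for one model/scenario.

    ``data`` is an ``xarray.DataArray`` with dims ``(time, lat, lon)``; the
    time coordinate is calendar-aware (cftime for non-standard calendars).
    Missing values are NaN.
    """

    variable: str
    data: xr.DataArray
    model_id: str = ""
    scenario_id: str = ""
    units: str = ""
    qc_counts: dict = dc_field(default_factory=dict)

    @property
    def grid(self) -> GridSpec:
        return GridSpec.from_dataset(self.data)

    @property
    def dates(self):
        return self.data["time"].values

    @property
    def calendar(self) -> str:
        t = self.data["time"].values
        if t.size and hasattr(t.flat[0], "calendar"):
            return t.flat[0].calendar
        return "standard"


def _open(path: str) -> xr.Dataset:
    try:
        coder = xr.coders.CFDatetimeCoder(use_cftime=True)
        return xr.open_dataset(path, decode_times=coder)
    except AttributeError:  # older xarray
        return xr.open_dataset(path, use_cftime=True)


def read_daily_fields(path_spec: str | list[str], variable: str,
                      grid: GridSpec | None = None) -> DailyClimateField:
    """Read one variable's daily fields from one or more NetCDF files.

    ``path_spec`` is a path, a glob pattern, or an explicit list of paths;
    files are concatenated along time and sorted by date.  Values are returned
    exactly as stored (no QC); units are recorded verbatim from metadata.

    Raises
    ------
    FormatError
        If a file lacks the variable or lat/lon/time coordinates.
    GridMismatchError
        If files (or the optional expected ``grid``) disagree on coordinates.
    """
    if isinstance(path_spec, (list, tuple)):
        paths = [str(p) for p in path_spec]
    else:
        paths = sorted(glob.glob(str(path_spec))) or [str(path_spec)]
    pieces = []
    meta = {}
    ref_grid = grid
    for path in paths:
        if not os.path.exists(path):
            raise FileNotFoundError(f"climate file not found: {path}")
        ds = _open(path)
        if variable not in ds:
            raise FormatError(f"variable {variable!r} not found in {path}")
        da = ds[variable]
        for coord in ("time", "lat", "lon"):
            if coord not in da.coords:
                raise FormatError(f"coordinate {coord!r} missing in {path}")
        g = GridSpec.from_dataset(da)
        if ref_grid is None:
            ref_grid = g
        elif not g.matches(ref_grid):
            raise GridMismatchError(f"grid of {path} differs from expected grid")
        if not meta:
            meta = {
                "units": str(da.attrs.get("units", "")),
                "model_id": str(ds.attrs.get("model_id", "")),
                "scenario_id": str(ds.attrs.get("scenario_id", "")),
            }
        pieces.append(da.load())
        ds.close()
    data = pieces[0] if len(pieces) == 1 else xr.concat(pieces, dim="time")
    data = data.sortby("time")
    return DailyClimateField(variable=variable, data=data, units=meta["units"],
                             model_id=meta["model_id"], scenario_id=meta["scenario_id"])


def write_daily_field(field: DailyClimateField, path: str) -> None:
    """Write a field back to NetCDF (float64, bit-stable round trip)."""
    da = field.data.astype("float64")
    da.attrs["units"] = field.units or VARIABLES.get(field.variable, "")
    ds = da.to_dataset(name=field.variable)
    ds.attrs["model_id"] = field.model_id
    ds.attrs["scenario_id"] = field.scenario_id
    if field.qc_counts:
        ds.attrs["history"] = (
            "qc_clean: sentinels->missing, variable-specific range rules; "
            + ", ".join(f"{k}={v}" for k, v in sorted(field.qc_counts.items()))
        )
    enc = {field.variable: {"dtype": "float64", "_FillValue": np.nan}}
    ds.to_netcdf(path, encoding=enc)


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------


def qc_clean(field: DailyClimateField) -> DailyClimateField:
    """Apply the archive quality-control rules to one daily field.

    Sentinel placeholders (|v| >= 1e19) become missing for every variable;
    then the variable-specific physical rule is applied (see module
    docstring).  All other values are unchanged.  The operation is idempotent
    and records per-rule replacement counts in ``qc_counts``.
    """
    if field.variable not in VARIABLES:
        raise ConfigurationError(f"unknown variable {field.variable!r}; "
                                 f"expected one of {sorted(VARIABLES)}")
    vals = field.data.values.astype("float64", copy=True)
    counts = {}
    sentinel = np.abs(vals) >= SENTINEL_THRESHOLD
    counts["sentinels_replaced"] = int(np.count_nonzero(sentinel))
    vals[sentinel] = np.nan
    if field.variable == "air_temperature":
        bad = vals <= 0.0  # kelvin: at or below absolute zero is unphysical
        counts["nonphysical_temperature_removed"] = int(np.count_nonzero(bad & np.isfinite(vals)))
        vals[bad] = np.nan
    elif field.variable == "relative_humidity":
        counts["humidity_clamped"] = int(np.count_nonzero((vals < 0) | (vals > 100)))
        np.clip(vals, 0.0, 100.0, out=vals)
    else:  # wind_speed, shortwave_radiation
        neg = vals < 0
        counts["negatives_zeroed"] = int(np.count_nonzero(neg))
        vals[neg] = 0.0
    data = field.data.copy(data=vals)
    return replace(field, data=data, qc_counts=counts)


# ---------------------------------------------------------------------------
# land mask
# ---------------------------------------------------------------------------


@dataclass
class LandMask:
    """Boolean land/ocean mask on a grid; True marks land."""

    grid: GridSpec
    is_land: np.ndarray

    def __post_init__(self):
        self.is_land = np.asarray(self.is_land, dtype=bool)
        if self.is_land.shape != self.grid.shape:
            raise GridMismatchError("mask shape does not match its grid")
        if not self.is_land.any():
            raise ValueError("land mask must contain at least one land cell")


def apply_land_mask(values, mask: LandMask):
    """Set non-land cells to missing; land cells are returned unchanged.

    ``values`` may be a 2-D array, a ``(time, lat, lon)`` array/DataArray or a
    ``DailyClimateField``; the trailing two dims must match the mask grid.
    """
    if isinstance(values, DailyClimateField):
        return replace(values, data=apply_land_mask(values.data, mask))
    if isinstance(values, xr.DataArray):
        _require_same_grid(GridSpec.from_dataset(values), mask.grid, "value grid vs mask")
        return values.where(xr.DataArray(mask.is_land, dims=("lat", "lon"),
                                         coords={"lat": mask.grid.lat, "lon": mask.grid.lon}))
    arr = np.asarray(values, dtype=float)
    if arr.shape[-2:] != mask.grid.shape:
        raise GridMismatchError("value shape does not match mask grid")
    out = arr.copy()
    out[..., ~mask.is_land] = np.nan
    return out
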
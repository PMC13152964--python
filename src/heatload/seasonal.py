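"""Seasonal climatological means per model and the equal-weighted ensemble.

Daily fields are averaged within each model over the days whose month falls
in a meteorological season (DJF/MAM/JJA/SON) and whose calendar year falls in
a named period; per-model climatologies are then combined into the
multi-model ensemble (MME) with equal weights.  Averaging the climate first
and computing the heat-load index from the ensemble-mean variables afterwards
is the default aggregation order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import xarray as xr

from .climate_io import DailyClimateField, GridSpec, VARIABLES

__all__ = [
    "Season", "SEASONS", "Period", "BUILTIN_PERIODS",
    "SeasonalClimatology", "EmptySelectionError", "ConsistencyError",
    "assign_season", "seasonal_mean_per_model", "build_climatology",
    "ensemble_mean",
]


class Season(NamedTuple):
    """A meteorological three-month season."""

    label: str
    months: frozenset


SEASONS: dict[str, Season] = {
    "DJF": Season("DJF", frozenset({12, 1, 2})),
    "MAM": Season("MAM", frozenset({3, 4, 5})),
    "JJA": Season("JJA", frozenset({6, 7, 8})),
    "SON": Season("SON", frozenset({9, 10, 11})),
}


class Period(NamedTuple):
    """An inclusive range of calendar years with a label."""

    label: str
    start_year: int
    end_year: int


#: the study's periods: 30-year climatological normal plus three 25-year windows
BUILTIN_PERIODS: dict[str, Period] = {
    "CliNo": Period("CliNo", 1985, 2014),
    "early": Period("early", 2026, 2050),
    "mid": Period("mid", 2051, 2075),
    "late": Period("late", 2076, 2100),
}


class EmptySelectionError(ValueError):
    """No days of a field fall in the requested period x season."""


class ConsistencyError(ValueError):
    """Climatologies being combined disagree on grid, period, season or scenario."""


def assign_season(date) -> Season:
    """Season of a (possibly cftime) date, determined by month only."""
    month = int(date.month)
    for season in SEASONS.values():
        if month in season.months:
            return season
    raise ValueError(f"month {month} outside 1..12")  # pragma: no cover


@dataclass
class SeasonalClimatology:
    """Per-season mean climate for one model (or the MME) over a period.

    ``means`` maps variable name -> 2-D DataArray (lat, lon); ``coverage``
    maps variable name -> fraction of selected days that contributed at each
    cell.  Means are missing wherever coverage fell below the configured
    minimum.
    """

    grid: GridSpec
    period: Period
    season: Season
    scenario_id: str
    source: str  # model id, or "MME"
    means: dict
    coverage: dict


def _season_time_index(field: DailyClimateField, period: Period, season: Season,
                       djf_spanning: bool = False) -> np.ndarray:
    times = field.data["time"].values
    months = np.array([t.month for t in times])
    years = np.array([t.year for t in times])
    if djf_spanning and season.label == "DJF":
        # December grouped with the following Jan/Feb: label Dec as year+1
        years = np.where(months == 12, years + 1, years)
    in_season = np.isin(months, list(season.months))
    in_period = (years >= period.start_year) & (years <= period.end_year)
    return in_season & in_period


def seasonal_mean_per_model(field: DailyClimateField, period: Period,
                            season: Season, min_coverage: float = 0.9,
                            djf_spanning: bool = False) -> xr.Dataset:
    """Per-cell mean of a daily field over one season within one period.

    The mean is the plain arithmetic mean over all non-missing selected days
    (every day weighted equally, whatever the model calendar).  A cell whose
    fraction of non-missing selected days is below ``min_coverage`` is set to
    missing.  Returns a Dataset with variables ``mean`` and ``coverage``.
    """
    sel = _season_time_index(field, period, season, djf_spanning)
    n_sel = int(np.count_nonzero(sel))
    if n_sel == 0:
        raise EmptySelectionError(
            f"no days of {field.variable} ({field.model_id}) fall in "
            f"{season.label} of {period.label} [{period.start_year}-{period.end_year}]")
    vals = field.data.values[sel]  # (n_sel, nlat, nlon)
    finite = np.isfinite(vals)
    n_ok = finite.sum(axis=0)
    total = np.where(finite, vals, 0.0).sum(axis=0)
    mean = np.where(n_ok > 0, total / np.maximum(n_ok, 1), np.nan)
    coverage = n_ok / n_sel
    mean = np.where(coverage >= min_coverage, mean, np.nan)
    coords = {"lat": field.data["lat"], "lon": field.data["lon"]}
    return xr.Dataset(
        {"mean": xr.DataArray(mean, dims=("lat", "lon"), coords=coords),
         "coverage": xr.DataArray(coverage, dims=("lat", "lon"), coords=coords)},
        attrs={"variable": field.variable, "season": season.label,
               "period": period.label, "n_days_selected": n_sel},
    )


def build_climatology(fields: Iterable[DailyClimateField], period: Period,
                      season: Season, min_coverage: float = 0.9,
                      djf_spanning: bool = False) -> SeasonalClimatology:
    """Assemble one model's SeasonalClimatology from its four daily fields."""
    fields = list(fields)
    if not fields:
        raise ValueError("no fields supplied")
    means, coverage = {}, {}
    for f in fields:
        sm = seasonal_mean_per_model(f, period, season, min_coverage, djf_spanning)
        means[f.variable] = sm["mean"]
        coverage[f.variable] = sm["coverage"]
    f0 = fields[0]
    return SeasonalClimatology(grid=f0.grid, period=period, season=season,
                               scenario_id=f0.scenario_id, source=f0.model_id,
                               means=means, coverage=coverage)


def ensemble_mean(climatologies: Sequence[SeasonalClimatology]) -> SeasonalClimatology:
    """Equal-weighted multi-model mean of per-model climatologies.

    At each cell and variable the unweighted arithmetic mean across models is
    taken, skipping models that are missing there; the result is missing only
    where all models are missing.  Invariant under the order of the inputs.
    """
    clims = list(climatologies)
    if not clims:
        raise ValueError("ensemble_mean requires at least one climatology")
    ref = clims[0]
    for c in clims[1:]:
        if (c.period != ref.period or c.season != ref.season
                or c.scenario_id != ref.scenario_id):
            raise ConsistencyError(
                f"cannot mix {c.source} ({c.period.label}/{c.season.label}/"
                f"{c.scenario_id}) with {ref.source} ({ref.period.label}/"
                f"{ref.season.label}/{ref.scenario_id})")
        if not c.grid.matches(ref.grid):
            raise ConsistencyError(f"model {c.source} is on a different grid")
    variables = sorted(set().union(*(c.means.keys() for c in clims)))
    means, coverage = {}, {}
    for var in variables:
        stack = np.stack([np.asarray(c.means[var], dtype=float) for c in clims
                          if var in c.means])
        cov = np.stack([np.asarray(c.coverage[var], dtype=float) for c in clims
                        if var in c.coverage])
        finite = np.isfinite(stack)
        n_ok = finite.sum(axis=0)
        mme = np.where(n_ok > 0,
                       np.where(finite, stack, 0.0).sum(axis=0) / np.maximum(n_ok, 1),
                       np.nan)
        coords = {"lat": ref.grid.lat, "lon": ref.grid.lon}
        means[var] = xr.DataArray(mme, dims=("lat", "lon"), coords=coords)
        coverage[var] = xr.DataArray(np.mean(cov, axis=0), dims=("lat", "lon"),
                                     coords=coords)
    return SeasonalClimatology(grid=ref.grid, period=ref.period, season=ref.season,
                               scenario_id=ref.scenario_id, source="MME",
                               means=means, coverage=coverage)
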
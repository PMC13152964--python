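"""Land-area accounting of extreme heat-stress exposure, globally and by country.

Cell areas on the lat-lon grid follow the spherical-zone formula

    A = R^2 * dlambda * (sin(phi_upper) - sin(phi_lower))      [km^2]

with R the mean Earth radius (6371 km) and dlambda the longitudinal width in
radians.  Countries are assigned to grid cells by cell-center containment in
their polygons.  The exposure statistic is the share of land area whose
seasonal-mean HLI falls in the Extreme category, and the change statistic is
the signed percentage-point (pp) difference of that share from the
climatological baseline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import shape as shapely_shape

from .climate_io import GridSpec, GridMismatchError, LandMask
from .hli import CategoryGrid

__all__ = [
    "EARTH_RADIUS_KM", "EXTREME_CODE",
    "RegionGrid", "GeometryError", "GapError",
    "cell_area", "cell_areas", "load_regions_geojson", "rasterize_regions",
    "extreme_share", "pp_change", "build_summary",
]

#: mean Earth radius used for all area computations
EARTH_RADIUS_KM = 6371.0
#: category code of the Extreme thermal-welfare band
EXTREME_CODE = 4
#: region id for cells assigned to no country polygon
UNASSIGNED = -1


class GeometryError(ValueError):
    """A region polygon is invalid or unusable."""


class GapError(ValueError):
    """A requested season/period/scenario combination has no category grid."""


# ---------------------------------------------------------------------------
# cell areas
# ---------------------------------------------------------------------------


def cell_area(lat_lower: float, lat_upper: float, lon_step: float,
              earth_radius: float = EARTH_RADIUS_KM) -> float:
    """Area (km^2) of one grid cell bounded by two latitudes.

    Spherical-zone formula: summing over a full-sphere grid recovers
    4*pi*R^2 exactly (up to floating round-off).
    """
    if not (-90.0 - 1e-9 <= lat_lower < lat_upper <= 90.0 + 1e-9):
        raise ValueError(f"invalid latitude bounds [{lat_lower}, {lat_upper}]")
    if lon_step <= 0:
        raise ValueError("lon_step must be positive")
    dlam = np.deg2rad(lon_step)
    return float(earth_radius ** 2 * dlam
                 * (np.sin(np.deg2rad(lat_upper)) - np.sin(np.deg2rad(lat_lower))))


def cell_areas(grid: GridSpec, earth_radius: float = EARTH_RADIUS_KM) -> np.ndarray:
    """Per-cell areas (km^2) for a whole grid, shape (nlat, nlon)."""
    lo, hi = grid.lat_bounds()
    row = (earth_radius ** 2 * np.deg2rad(grid.lon_step)
           * (np.sin(np.deg2rad(hi)) - np.sin(np.deg2rad(lo))))
    return np.repeat(row[:, None], grid.lon.size, axis=1)


# ---------------------------------------------------------------------------
# country rasterization
# ---------------------------------------------------------------------------


@dataclass
class RegionGrid:
    """Per-cell region id (-1 where unassigned) with an id -> name table."""

    grid: GridSpec
    region_id: np.ndarray
    names: dict

    def __post_init__(self):
        self.region_id = np.asarray(self.region_id, dtype=int)
        if self.region_id.shape != self.grid.shape:
            raise GridMismatchError("region_id shape does not match grid")


def load_regions_geojson(path_or_obj) -> list[tuple[int, str, object]]:
    """Read (id, name, geometry) triples from a GeoJSON FeatureCollection.

    Features must carry ``region_id`` (int) and ``name`` properties; standard
    country layers can be adapted by renaming their code attribute.
    """
    if isinstance(path_or_obj, dict):
        obj = path_or_obj
    else:
        with open(path_or_obj) as fh:
            obj = json.load(fh)
    regions = []
    for feat in obj.get("features", []):
        props = feat.get("properties", {})
        rid = int(props["region_id"])
        name = str(props.get("name", str(rid)))
        geom = shapely_shape(feat["geometry"])
        regions.append((rid, name, geom))
    return regions


def rasterize_regions(regions, grid: GridSpec) -> RegionGrid:
    """Assign each grid cell to the region polygon containing its center.

    ``regions`` is an iterable of (id, name, shapely geometry).  Cells whose
    center falls in no polygon stay unassigned (-1).  If polygons overlap,
    the first region in input order wins, which keeps the assignment
    deterministic.
    """
    lon2d, lat2d = np.meshgrid(grid.lon, grid.lat)
    region_id = np.full(grid.shape, UNASSIGNED, dtype=int)
    names = {}
    for rid, name, geom in regions:
        if geom is None or geom.is_empty:
            raise GeometryError(f"region {name!r} ({rid}) has empty geometry")
        if not geom.is_valid:
            raise GeometryError(f"region {name!r} ({rid}) has invalid geometry")
        names[int(rid)] = name
        inside = shapely.contains_xy(geom, lon2d.ravel(), lat2d.ravel())
        inside = inside.reshape(grid.shape) & (region_id == UNASSIGNED)
        region_id[inside] = int(rid)
    return RegionGrid(grid=grid, region_id=region_id, names=names)


# ---------------------------------------------------------------------------
# exposure shares
# ---------------------------------------------------------------------------


def extreme_share(categories: CategoryGrid, areas: np.ndarray, mask: LandMask,
                  region: np.ndarray | None = None) -> float:
    """Percent of land area in the Extreme category, within a region.

    ``region`` is an optional boolean cell selector (None means global, i.e.
    all land cells of the grid).  Returns NaN for a region with zero land
    area.  Ocean cells never enter numerator or denominator.
    """
    if not categories.grid.matches(mask.grid):
        raise GridMismatchError("category grid does not match land-mask grid")
    areas = np.asarray(areas, dtype=float)
    if areas.shape != categories.grid.shape:
        raise GridMismatchError("cell-area shape does not match category grid")
    codes = np.asarray(categories.codes)
    land = mask.is_land.copy()
    if region is not None:
        land &= np.asarray(region, dtype=bool)
    denom = areas[land].sum()
    if denom <= 0:
        return float("nan")
    num = areas[land & (codes == EXTREME_CODE)].sum()
    return float(100.0 * num / denom)


def pp_change(projected_share: float, baseline_share: float) -> float:
    """Signed percentage-point difference, projected minus baseline."""
    return float(projected_share) - float(baseline_share)


def build_summary(category_grids: dict, baseline_grids: dict,
                  areas: np.ndarray, mask: LandMask,
                  regions: RegionGrid | None = None,
                  seasons=("DJF", "MAM", "JJA", "SON"),
                  periods=("early", "mid", "late"),
                  scenarios=("ssp126", "ssp245", "ssp370", "ssp585"),
                  baseline_label: str = "CliNo") -> pd.DataFrame:
    """Tabulate Extreme-share percent and pp change for every combination.

    ``category_grids`` maps ``(season, period, scenario)`` to a CategoryGrid;
    ``baseline_grids`` maps ``season`` to the baseline CategoryGrid.  One row
    is produced per region x season x (baseline + period x scenario); the
    global region is always included.  Shares are kept at full precision;
    round only at presentation time.

    Raises ``GapError`` listing every missing combination rather than
    silently omitting rows.
    """
    gaps = [s for s in seasons if s not in baseline_grids]
    gaps += [(s, p, sc) for s in seasons for p in periods for sc in scenarios
             if (s, p, sc) not in category_grids]
    if gaps:
        raise GapError(f"missing category grids for: {gaps}")

    region_list: list[tuple[int | str, str, np.ndarray | None]] = [
        ("GLOBAL", "Global", None)]
    if regions is not None:
        for rid in sorted(regions.names):
            region_list.append((rid, regions.names[rid], regions.region_id == rid))

    rows = []
    for rid, rname, selector in region_list:
        for season in seasons:
            base = extreme_share(baseline_grids[season], areas, mask, selector)
            rows.append({"region_id": rid, "region_name": rname,
                         "season": season, "period": baseline_label,
                         "scenario": "historical",
                         "extreme_share_pct": base, "pp_change": 0.0})
            for period in periods:
                for scen in scenarios:
                    share = extreme_share(category_grids[(season, period, scen)],
                                          areas, mask, selector)
                    rows.append({"region_id": rid, "region_name": rname,
                                 "season": season, "period": period,
                                 "scenario": scen,
                                 "extreme_share_pct": share,
                                 "pp_change": pp_change(share, base)})
    return pd.DataFrame(rows)
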
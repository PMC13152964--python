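"""Cell areas, country rasterization and extreme-exposure accounting."""

import math

import numpy as np
import pytest
import xarray as xr
from shapely.geometry import Polygon, box

from heatload import (EARTH_RADIUS_KM, GapError, GeometryError, GridSpec,
                      LandMask, RegionGrid, build_summary, cell_area,
                      cell_areas, extreme_share, pp_change, rasterize_regions)
from heatload.hli import CategoryGrid


def zone_area(lo, hi, dlon, r=EARTH_RADIUS_KM):
    # independent evaluation of the spherical-zone formula via the math module
    return r * r * math.radians(dlon) * (math.sin(math.radians(hi))
                                         - math.sin(math.radians(lo)))


class TestCellArea:
    def test_equatorial_quarter_degree_cell(self):
        got = cell_area(-0.125, 0.125, 0.25)
        assert got == pytest.approx(zone_area(-0.125, 0.125, 0.25), rel=1e-12)
        assert got == pytest.approx(772.6, abs=0.2)

    def test_full_sphere_recovered(self):
        grid = GridSpec.regular(720, 1440, -89.875, -179.875, 0.25)
        total = cell_areas(grid).sum()
        sphere = 4 * math.pi * EARTH_RADIUS_KM ** 2
        assert abs(total - sphere) / sphere < 1e-9

    def test_mirrored_cells_equal(self):
        north = cell_area(40.0, 40.25, 0.25)
        south = cell_area(-40.25, -40.0, 0.25)
        assert north == pytest.approx(south, rel=1e-12)

    def test_area_decreases_toward_poles(self):
        grid = GridSpec.regular(720, 4, -89.875, 0.125, 0.25)
        col = cell_areas(grid)[:, 0]
        south, north = col[:360], col[360:]
        assert np.all(np.diff(south) > 0) and np.all(np.diff(north) < 0)

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError):
            cell_area(10.0, 5.0, 0.25)
        with pytest.raises(ValueError):
            cell_area(0.0, 1.0, -0.25)


class TestRasterize:
    GRID = GridSpec.regular(4, 4, 0.125, 0.125)  # centers 0.125 .. 0.875

    def test_rectangle_covering_four_centers(self):
        # covers the 2x2 block of centers (0.125, 0.375) x (0.125, 0.375)
        rect = box(0.0, 0.0, 0.5, 0.5)
        rg = rasterize_regions([(1, "R", rect)], self.GRID)
        assert (rg.region_id == 1).sum() == 4
        assert (rg.region_id[:2, :2] == 1).all()

    def test_center_outside_all_polygons_unassigned(self):
        rect = box(10.0, 10.0, 11.0, 11.0)
        rg = rasterize_regions([(1, "R", rect)], self.GRID)
        assert (rg.region_id == -1).all()

    def test_disjoint_polygons_get_disjoint_cells(self):
        a = box(0.0, 0.0, 0.5, 1.0)
        b = box(0.5, 0.0, 1.0, 1.0)
        rg = rasterize_regions([(1, "A", a), (2, "B", b)], self.GRID)
        assert ((rg.region_id == 1) & (rg.region_id == 2)).sum() == 0
        assert (rg.region_id == 1).sum() == 8 and (rg.region_id == 2).sum() == 8

    def test_overlap_resolved_by_input_order(self):
        a = box(0.0, 0.0, 1.0, 1.0)
        b = box(0.0, 0.0, 1.0, 1.0)
        rg = rasterize_regions([(1, "A", a), (2, "B", b)], self.GRID)
        assert (rg.region_id == 1).all()

    def test_invalid_geometry_names_region(self):
        bowtie = Polygon([(0, 0), (1, 1), (1, 0), (0, 1)])
        with pytest.raises(GeometryError, match="Bow"):
            rasterize_regions([(9, "Bow", bowtie)], self.GRID)


def category_grid(codes, grid):
    return CategoryGrid(grid=grid, season="JJA", period="p", scenario_id="s",
                        codes=xr.DataArray(np.asarray(codes, dtype=np.int8),
                                           dims=("lat", "lon"),
                                           coords={"lat": grid.lat,
                                                   "lon": grid.lon}))


class TestExtremeShare:
    # 2x2 grid mirrored about the equator: all four cells have equal area
    GRID = GridSpec.regular(2, 2, -0.125, 0.125)

    def mask(self, is_land=None):
        if is_land is None:
            is_land = np.ones((2, 2), bool)
        return LandMask(self.GRID, is_land)

    def test_one_of_four_equal_cells(self):
        cats = category_grid([[4, 0], [0, 0]], self.GRID)
        share = extreme_share(cats, cell_areas(self.GRID), self.mask())
        assert share == pytest.approx(25.0, abs=1e-12)

    def test_none_and_all_extreme(self):
        areas = cell_areas(self.GRID)
        assert extreme_share(category_grid(np.zeros((2, 2)), self.GRID),
                             areas, self.mask()) == 0.0
        assert extreme_share(category_grid(np.full((2, 2), 4), self.GRID),
                             areas, self.mask()) == 100.0

    def test_ocean_cells_excluded_from_denominator(self):
        cats = category_grid([[4, 0], [0, 0]], self.GRID)
        land = np.array([[True, True], [False, False]])
        share = extreme_share(cats, cell_areas(self.GRID), self.mask(land))
        assert share == pytest.approx(50.0, abs=1e-12)

    def test_relabelling_non_extreme_categories_is_irrelevant(self):
        areas = cell_areas(self.GRID)
        a = extreme_share(category_grid([[4, 1], [2, 3]], self.GRID), areas, self.mask())
        b = extreme_share(category_grid([[4, 0], [0, 0]], self.GRID), areas, self.mask())
        assert a == b

    def test_zero_land_region_is_undefined(self):
        cats = category_grid([[4, 0], [0, 0]], self.GRID)
        land = np.array([[True, True], [True, False]])
        region = np.array([[False, False], [False, True]])  # ocean-only region
        share = extreme_share(cats, cell_areas(self.GRID), self.mask(land), region)
        assert math.isnan(share)

    def test_global_share_is_area_weighted_mean_of_partition(self):
        grid = GridSpec.regular(6, 4, -0.625, 0.125)
        rng = np.random.default_rng(8)
        cats = category_grid(rng.integers(0, 5, grid.shape), grid)
        areas = cell_areas(grid)
        mask = LandMask(grid, np.ones(grid.shape, bool))
        top = np.zeros(grid.shape, bool)
        top[:3] = True
        shares, weights = [], []
        for region in (top, ~top):
            shares.append(extreme_share(cats, areas, mask, region))
            weights.append(areas[region].sum())
        combined = np.average(shares, weights=weights)
        global_share = extreme_share(cats, areas, mask)
        assert global_share == pytest.approx(combined, rel=1e-12)


class TestPpChange:
    def test_values(self):
        assert pp_change(40.0, 30.0) == pytest.approx(10.0)
        assert pp_change(33.3, 33.3) == 0.0
        assert pp_change(39.5, 31.2) == pytest.approx(8.3)

    def test_antisymmetric(self):
        assert pp_change(12.0, 37.5) == -pp_change(37.5, 12.0)


class TestBuildSummary:
    GRID = GridSpec.regular(2, 2, -0.125, 0.125)

    def _grids(self, seasons, periods, scenarios):
        base = {s: category_grid([[4, 0], [0, 0]], self.GRID) for s in seasons}
        proj = {(s, p, sc): category_grid([[4, 4], [0, 0]], self.GRID)
                for s in seasons for p in periods for sc in scenarios}
        return base, proj

    def test_global_row_count_and_pp(self):
        seasons = ("DJF", "MAM", "JJA", "SON")
        periods = ("early", "mid", "late")
        scenarios = ("ssp126", "ssp245", "ssp370", "ssp585")
        base, proj = self._grids(seasons, periods, scenarios)
        mask = LandMask(self.GRID, np.ones((2, 2), bool))
        df = build_summary(proj, base, cell_areas(self.GRID), mask,
                           seasons=seasons, periods=periods, scenarios=scenarios)
        assert len(df) == 4 * (1 + 3 * 4)  # 52 rows, global only
        baseline = df[df["scenario"] == "historical"]
        assert (baseline["pp_change"] == 0.0).all()
        assert (baseline["extreme_share_pct"] == 25.0).all()
        projected = df[df["scenario"] != "historical"]
        assert projected["extreme_share_pct"].unique() == [50.0]
        assert projected["pp_change"].unique() == [25.0]

    def test_each_region_adds_a_full_block_of_rows(self):
        seasons, periods, scenarios = ("JJA",), ("late",), ("ssp585",)
        base, proj = self._grids(seasons, periods, scenarios)
        mask = LandMask(self.GRID, np.ones((2, 2), bool))
        one = RegionGrid(self.GRID, np.array([[1, 1], [-1, -1]]), {1: "A"})
        two = RegionGrid(self.GRID, np.array([[1, 1], [2, 2]]), {1: "A", 2: "B"})
        n_global = len(build_summary(proj, base, cell_areas(self.GRID), mask,
                                     seasons=seasons, periods=periods,
                                     scenarios=scenarios))
        n_one = len(build_summary(proj, base, cell_areas(self.GRID), mask, one,
                                  seasons=seasons, periods=periods,
                                  scenarios=scenarios))
        n_two = len(build_summary(proj, base, cell_areas(self.GRID), mask, two,
                                  seasons=seasons, periods=periods,
                                  scenarios=scenarios))
        assert n_one == 2 * n_global
        assert n_two == 3 * n_global

    def test_missing_combination_reported_not_dropped(self):
        seasons, periods, scenarios = ("JJA", "DJF"), ("late",), ("ssp585",)
        base, proj = self._grids(seasons, periods, scenarios)
        del proj[("DJF", "late", "ssp585")]
        mask = LandMask(self.GRID, np.ones((2, 2), bool))
        with pytest.raises(GapError, match="DJF"):
            build_summary(proj, base, cell_areas(self.GRID), mask,
                          seasons=seasons, periods=periods, scenarios=scenarios)
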
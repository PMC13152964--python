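"""Black-globe temperature, the two-branch HLI and welfare classification."""

import math

import numpy as np
import pytest
import xarray as xr
from hypothesis import given, settings, strategies as st

from heatload import (CATEGORY_NAMES, ClassificationError, GridSpec, Period,
                      SEASONS, classify_hli, compute_bgt, compute_hli,
                      hli_from_climatology)
from heatload.hli import MISSING_CATEGORY, WELFARE_CATEGORIES
from heatload.seasonal import SeasonalClimatology


def oracle_chain(ta, sr, rh, ws):
    """Independent straight-line evaluation of BGT -> HLI (pure math module)."""
    bgt = 1.33 * ta - 2.65 * math.sqrt(ta) + 3.21 * math.log10(sr + 1.0) + 3.5
    if bgt >= 25.0:
        return 8.62 + 0.38 * rh + 1.55 * bgt - 0.5 * ws + math.exp(2.4 - ws)
    return 10.66 + 0.28 * rh + 1.3 * bgt - ws


class TestBgt:
    @pytest.mark.parametrize("ta,sr,expected", [
        (25.0, 0.0, 23.5),
        (25.0, 999.0, 33.13),   # log10(1000) = 3
    ])
    def test_hand_values(self, ta, sr, expected):
        assert compute_bgt(ta, sr) == pytest.approx(expected, abs=1e-9)

    def test_zero_radiation_term_vanishes(self):
        for ta in (0.0, 5.0, 30.0):
            assert compute_bgt(ta, 0.0) == pytest.approx(
                1.33 * ta - 2.65 * math.sqrt(ta) + 3.5, abs=1e-12)

    def test_subzero_air_temperature_is_missing(self):
        assert np.isnan(compute_bgt(-0.1, 100.0))
        out = compute_bgt(np.array([-5.0, 10.0]), np.array([0.0, 0.0]))
        assert np.isnan(out[0]) and np.isfinite(out[1])

    def test_strictly_increasing_in_radiation(self):
        sr = np.linspace(0, 1200, 400)
        vals = compute_bgt(20.0, sr)
        assert np.all(np.diff(vals) > 0)

    def test_increasing_in_temperature_above_stationary_point(self):
        # d/dTa (1.33 Ta - 2.65 sqrt(Ta)) = 0 at Ta = (2.65 / 2.66)^2 ~ 0.993
        ta_star = (2.65 / (2 * 1.33)) ** 2
        ta = np.linspace(ta_star + 1e-3, 50, 500)
        assert np.all(np.diff(compute_bgt(ta, 300.0)) > 0)
        # below it the empirical fit is non-monotonic: not asserted, documented
        low = compute_bgt(np.array([0.0, ta_star]), np.array([0.0, 0.0]))
        assert low[0] > low[1]


class TestHli:
    @pytest.mark.parametrize("bgt,rh,ws,expected", [
        (20.0, 50.0, 2.0, 48.66),                          # lower branch
        (30.0, 50.0, 2.0, 73.12 + math.exp(0.4)),          # upper branch
    ])
    def test_hand_values(self, bgt, rh, ws, expected):
        assert compute_hli(bgt, rh, ws) == pytest.approx(expected, abs=1e-9)

    def test_branch_boundary_uses_upper_at_equality(self):
        upper = 8.62 + 0.38 * 50 + 1.55 * 25.0 - 0.5 * 2 + math.exp(0.4)
        assert compute_hli(25.0, 50.0, 2.0) == pytest.approx(upper, abs=1e-12)
        # the two branches do not agree at the boundary: document the jump
        lower = 10.66 + 0.28 * 50 + 1.3 * 25.0 - 2.0
        assert abs(upper - lower) > 1.0

    def test_high_wind_limit_kills_exponential(self):
        h1 = compute_hli(30.0, 50.0, 20.0)
        linear = 8.62 + 0.38 * 50 + 1.55 * 30 - 0.5 * 20
        assert h1 == pytest.approx(linear, abs=1e-7)

    def test_missing_inputs_propagate(self):
        assert np.isnan(compute_hli(np.nan, 50.0, 2.0))
        assert np.isnan(compute_hli(30.0, np.nan, 2.0))
        assert np.isnan(compute_hli(30.0, 50.0, np.nan))

    def test_monotonicity_by_finite_differences(self):
        rng = np.random.default_rng(2)
        n = 300
        bgt = np.concatenate([rng.uniform(-5, 24.5, n), rng.uniform(25, 45, n)])
        rh = rng.uniform(0, 100, 2 * n)
        ws = rng.uniform(0, 15, 2 * n)
        h = 1e-4  # small enough that no sample crosses the branch boundary
        assert np.all(compute_hli(bgt, rh + h, ws) > compute_hli(bgt, rh, ws))
        assert np.all(compute_hli(bgt + h, rh, ws) > compute_hli(bgt, rh, ws))
        assert np.all(compute_hli(bgt, rh, ws + h) < compute_hli(bgt, rh, ws))

    def test_chain_matches_independent_oracle(self):
        rng = np.random.default_rng(42)
        n = 10_000
        ta = rng.uniform(0, 45, n)
        sr = rng.uniform(0, 1100, n)
        rh = rng.uniform(0, 100, n)
        ws = rng.uniform(0, 15, n)
        ours = compute_hli(compute_bgt(ta, sr), rh, ws)
        theirs = np.array([oracle_chain(*args) for args in zip(ta, sr, rh, ws)])
        np.testing.assert_allclose(ours, theirs, atol=1e-9, rtol=0)


class TestClassification:
    @pytest.mark.parametrize("value,code", [
        (-50.0, 0), (70.0, 0), (70.01, 1), (77.0, 1), (77.5, 2),
        (86.0, 2), (86.5, 3), (96.0, 3), (96.01, 4), (150.0, 4),
    ])
    def test_boundaries_belong_to_lower_category(self, value, code):
        assert classify_hli(value) == code

    def test_nonfinite_scalar_raises(self):
        with pytest.raises(ClassificationError):
            classify_hli(float("nan"))

    def test_nonfinite_array_entries_marked_missing(self):
        out = classify_hli(np.array([50.0, np.nan, 100.0]))
        assert list(out) == [0, MISSING_CATEGORY, 4]

    @settings(max_examples=300, deadline=None)
    @given(st.one_of(st.floats(-50, 150, allow_nan=False),
                     st.sampled_from([70.0, 77.0, 86.0, 96.0])))
    def test_exactly_one_category_fires(self, x):
        hits = [c for c in WELFARE_CATEGORIES if c.lower < x <= c.upper]
        assert len(hits) == 1
        assert hits[0].code == classify_hli(x)
        assert hits[0].name == CATEGORY_NAMES[hits[0].code]


def uniform_climatology(ta=25.0, rh=50.0, sr=0.0, ws=2.0, shape=(2, 3)):
    grid = GridSpec.regular(shape[0], shape[1], 0.125, 0.125)
    coords = {"lat": grid.lat, "lon": grid.lon}
    mk = lambda v: xr.DataArray(np.full(shape, float(v)), dims=("lat", "lon"),
                                coords=coords)
    return SeasonalClimatology(grid=grid, period=Period("p", 2000, 2000),
                               season=SEASONS["JJA"], scenario_id="s",
                               source="MME",
                               means={"air_temperature": mk(ta),
                                      "relative_humidity": mk(rh),
                                      "shortwave_radiation": mk(sr),
                                      "wind_speed": mk(ws)},
                               coverage={})


class TestFromClimatology:
    def test_uniform_chain_value_and_category(self):
        field, cats = hli_from_climatology(uniform_climatology())
        # BGT(25, 0) = 23.5 < 25 -> lower branch: 10.66 + 14 + 30.55 - 2
        np.testing.assert_allclose(field.hli.values, 53.21, atol=1e-9)
        assert (cats.codes.values == 0).all()

    def test_kelvin_input_converted(self):
        field, _ = hli_from_climatology(uniform_climatology(ta=25.0 + 273.15))
        np.testing.assert_allclose(field.hli.values, 53.21, atol=1e-9)

    def test_missing_cell_propagates(self):
        clim = uniform_climatology()
        v = clim.means["relative_humidity"].values.copy()
        v[0, 1] = np.nan
        clim.means["relative_humidity"] = clim.means["relative_humidity"].copy(data=v)
        field, cats = hli_from_climatology(clim)
        assert np.isnan(field.hli.values[0, 1])
        assert cats.codes.values[0, 1] == MISSING_CATEGORY
        assert np.isfinite(field.hli.values[0, 0])

    def test_missing_variable_rejected(self):
        clim = uniform_climatology()
        del clim.means["wind_speed"]
        with pytest.raises(ValueError, match="wind_speed"):
            hli_from_climatology(clim)

    def test_subzero_temperature_policy(self):
        clim = uniform_climatology(ta=-10.0)
        field, cats = hli_from_climatology(clim, subzero="comfort")
        assert (cats.codes.values == 0).all()
        assert np.isnan(field.bgt.values).all()
        _, cats2 = hli_from_climatology(clim, subzero="missing")
        assert (cats2.codes.values == MISSING_CATEGORY).all()

    def test_deterministic(self):
        a = hli_from_climatology(uniform_climatology(ta=31.0, sr=500.0))
        b = hli_from_climatology(uniform_climatology(ta=31.0, sr=500.0))
        np.testing.assert_array_equal(a[0].hli.values, b[0].hli.values)
        np.testing.assert_array_equal(a[1].codes.values, b[1].codes.values)
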
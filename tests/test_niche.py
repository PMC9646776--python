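import numpy as np
import pandas as pd
import pytest
import xarray as xr
from hypothesis import given, settings
from hypothesis import strategies as st

from fishclim import niche
from fishclim.niche import (NicheParameters, annualize, bathymetric_suitability,
                            climatology_map, combine_suitabilities, mdssb_daily,
                            regional_series, thermal_suitability,
                            trophic_suitability)

PARAMS = NicheParameters()


class TestNicheParameters:
    @pytest.mark.parametrize("bad", [
        dict(t1=0), dict(t2=-1), dict(c=0), dict(c=1.5),
        dict(theta2=-1), dict(theta3=700), dict(chl_min=-0.1),
        dict(window_days=0),
    ])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            NicheParameters(**bad)


class TestThermalSuitability:
    @pytest.mark.parametrize("y, expected", [
        (5.4, 1.0),                                  # value at the optimum is c
        (-0.3, np.exp(-0.5)),                        # one sigma below (y_opt - t1)
        (9.4, np.exp(-0.5)),                         # one sigma above (y_opt + t2)
        (20.0, np.exp(-(14.6**2) / (2 * 4.0**2))),   # far warm tail
    ])
    def test_closed_form(self, y, expected):
        assert thermal_suitability(y, PARAMS) == pytest.approx(expected, rel=1e-12)

    def test_non_finite_input_maps_to_missing(self):
        out = thermal_suitability(np.array([np.nan, np.inf, 5.4]), PARAMS)
        assert np.isnan(out[0]) and np.isnan(out[1]) and out[2] == 1.0

    @given(st.floats(min_value=-2, max_value=35))
    @settings(max_examples=200, deadline=None)
    def test_bounded_and_maximal_at_optimum(self, y):
        u = thermal_suitability(y, PARAMS)
        assert 0 < u <= PARAMS.c
        assert u <= thermal_suitability(PARAMS.y_opt, PARAMS)

    def test_strictly_decreasing_away_from_optimum(self):
        warm = thermal_suitability(np.linspace(5.4, 20, 50), PARAMS)
        cold = thermal_suitability(np.linspace(5.4, -2, 50), PARAMS)
        assert np.all(np.diff(warm) < 0)
        assert np.all(np.diff(cold) < 0)


class TestBathymetricSuitability:
    @pytest.mark.parametrize("z, expected", [
        (100.0, 1.0),     # plateau
        (400.0, 0.5),     # midpoint of the descending ramp (600-400)/(600-200)
        (650.0, 0.0),     # beyond theta4
        (5e-5, 0.5),      # midpoint of the (near-step) ascending ramp
        (-10.0, 0.0),     # land: negative depth via the z <= theta1 branch
        (600.0, 0.0),     # boundary exactly at theta4
    ])
    def test_trapezoid_values(self, z, expected):
        assert bathymetric_suitability(z, PARAMS) == pytest.approx(expected)

    def test_ramp_midpoint_is_half_plateau(self):
        p = NicheParameters(theta1=50, theta2=100, theta3=200, theta4=400)
        assert bathymetric_suitability(75, p) == pytest.approx(0.5)
        assert bathymetric_suitability(300, p) == pytest.approx(0.5)

    def test_zero_width_ramp_is_step(self):
        p = NicheParameters(theta1=100, theta2=100, theta3=200, theta4=200)
        assert bathymetric_suitability(100, p) == 0.0
        assert bathymetric_suitability(150, p) == 1.0
        assert bathymetric_suitability(200, p) == 0.0

    def test_nan_propagates(self):
        assert np.isnan(bathymetric_suitability(np.nan, PARAMS))


class TestTrophicSuitability:
    def test_qualifying_run_scores_member_days_only(self):
        chl = np.full(60, 0.04)
        chl[20:40] = 0.06  # 20 consecutive days above threshold
        out = trophic_suitability(chl, PARAMS)
        assert np.all(out[20:40] == 1)
        assert np.all(np.delete(out, slice(20, 40)) == 0)

    def test_below_threshold_everywhere_is_zero(self):
        assert np.all(trophic_suitability(np.full(100, 0.04), PARAMS) == 0)

    def test_run_shorter_than_window_scores_zero(self):
        chl = np.full(60, 0.01)
        chl[10:24] = 0.10  # exactly 14 days < window_days = 15
        assert np.all(trophic_suitability(chl, PARAMS) == 0)

    def test_threshold_is_inclusive(self):
        chl = np.full(30, 0.05)
        assert np.all(trophic_suitability(chl, PARAMS) == 1)

    def test_short_series_warns_and_zeroes(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="fishclim.niche"):
            out = trophic_suitability(np.full(5, 0.9), PARAMS)
        assert np.all(out == 0)
        assert any("window_days" in r.message for r in caplog.records)

    def test_gridded_axis_handling(self):
        chl = np.full((60, 2, 2), 0.04)
        chl[20:40, 0, 0] = 0.06
        out = trophic_suitability(chl, PARAMS, axis=0)
        assert out[25, 0, 0] == 1 and out[25, 1, 1] == 0


class TestCombine:
    @pytest.mark.parametrize("components, expected", [
        ((1.0, 1.0, 1.0), 1.0),
        ((0.8, 0.5, 1.0), 0.4),
        ((0.9, 0.9, 0.0), 0.0),  # multiplicative nil rule
    ])
    def test_product(self, components, expected):
        assert combine_suitabilities(components) == pytest.approx(expected)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            combine_suitabilities([])

    def test_bounds_on_random_components(self, rng):
        u = rng.random((3, 50))
        k = combine_suitabilities(list(u))
        assert np.all((0 <= k) & (k <= 1))
        assert np.all(k <= u.min(axis=0) + 1e-15)


def _tiny_env(sst_val=5.4, depth_val=100.0, chl_fn=None, n_days=365):
    lat = np.array([54.0, 54.5])
    lon = np.array([2.0, 2.5])
    days = pd.date_range("2000-01-01", periods=n_days, freq="D")
    sst = xr.DataArray(np.full((n_days, 2, 2), sst_val),
                       coords={"time": days, "latitude": lat, "longitude": lon},
                       dims=("time", "latitude", "longitude"))
    chl_series = chl_fn(n_days) if chl_fn else np.full(n_days, 0.06)
    chl = xr.DataArray(np.broadcast_to(chl_series[:, None, None], (n_days, 2, 2)).copy(),
                       coords=sst.coords, dims=sst.dims)
    depth = xr.DataArray(np.full((2, 2), depth_val),
                         coords={"latitude": lat, "longitude": lon},
                         dims=("latitude", "longitude"))
    return niche.EnvironmentalFields(sst=sst, chl=chl, depth=depth)


class TestMdssbDaily:
    def test_composition_of_the_three_niches(self):
        def bloom(n):
            c = np.full(n, 0.04)
            c[100:120] = 0.06
            return c
        env = _tiny_env(sst_val=5.4, depth_val=100.0, chl_fn=bloom)
        k = mdssb_daily(env)
        assert np.all(k.values[100:120] == 1.0)
        assert np.all(np.delete(k.values, slice(100, 120), axis=0) == 0.0)

    def test_unsuitable_depth_gives_zero(self):
        env = _tiny_env(depth_val=700.0)
        assert float(mdssb_daily(env).max()) == 0.0

    def test_low_chlorophyll_gives_zero(self):
        env = _tiny_env(chl_fn=lambda n: np.full(n, 0.01))
        assert float(mdssb_daily(env).max()) == 0.0

    def test_missing_sst_propagates(self):
        env = _tiny_env()
        env.sst.values[0, 0, 0] = np.nan
        k = mdssb_daily(env)
        assert np.isnan(k.values[0, 0, 0])
        assert not np.isnan(k.values[0, 1, 1])

    def test_grid_mismatch_is_an_error(self):
        env = _tiny_env()
        bad_depth = env.depth.assign_coords(longitude=env.depth["longitude"] + 1.0)
        with pytest.raises(ValueError, match="longitude"):
            niche.EnvironmentalFields(sst=env.sst, chl=env.chl, depth=bad_depth)

    def test_chlorophyll_rescaling_above_threshold_leaves_k_unchanged(self):
        env = _tiny_env()
        k1 = annualize(mdssb_daily(env))
        env2 = niche.EnvironmentalFields(sst=env.sst, chl=env.chl * 3.0, depth=env.depth)
        k2 = annualize(mdssb_daily(env2))
        np.testing.assert_allclose(k1.values, k2.values)


class TestAnnualize:
    def _daily(self, values, year=2001):
        days = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
        return xr.DataArray(values, coords={"time": days}, dims=("time",))

    def test_constant_field(self):
        da = self._daily(np.full(365, 0.6))
        assert annualize(da).item() == pytest.approx(0.6)

    def test_half_days_high(self):
        days = pd.date_range("2001-01-01", "2001-12-31", freq="D")
        in_season = days.month.isin(range(3, 11))
        vals = np.zeros(365)
        idx = np.flatnonzero(in_season)
        vals[idx[: len(idx) // 2]] = 1.0
        da = xr.DataArray(vals, coords={"time": days}, dims=("time",))
        # 245 in-season days: 122 ones -> 122/245
        assert annualize(da).item() == pytest.approx(122 / 245)

    def test_all_missing_is_missing(self):
        da = self._daily(np.full(365, np.nan))
        assert np.isnan(annualize(da).item())

    def test_month_selection(self):
        days = pd.date_range("2001-01-01", "2001-12-31", freq="D")
        vals = np.where(days.month == 6, 1.0, 0.0)
        da = xr.DataArray(vals, coords={"time": days}, dims=("time",))
        assert annualize(da, months={6}).item() == 1.0


class TestRegionalAndClimatology:
    def _annual(self, data, years=(2000, 2001)):
        lat = np.array([51.5, 52.5])
        lon = np.array([1.0, 2.0])
        return xr.DataArray(data, coords={"year": list(years), "latitude": lat,
                                          "longitude": lon},
                            dims=("year", "latitude", "longitude"))

    def test_uniform_field(self):
        series = regional_series(self._annual(np.full((2, 2, 2), 0.7)), (51, 53, 0, 3))
        assert np.allclose(series.values, 0.7)

    def test_half_box_high(self):
        data = np.zeros((2, 2, 2))
        data[:, :, 0] = 1.0
        series = regional_series(self._annual(data), (51, 53, 0, 3))
        assert np.allclose(series.values, 0.5)

    def test_bbox_outside_grid_errors(self):
        with pytest.raises(ValueError):
            regional_series(self._annual(np.full((2, 2, 2), 0.7)), (80, 85, 0, 3))

    def test_bbox_membership_on_cell_centres(self):
        data = np.zeros((2, 2, 2))
        data[:, 1, :] = 1.0  # lat 52.5 row
        series = regional_series(self._annual(data), (52.5, 53.5, 0, 3))
        assert np.allclose(series.values, 1.0)

    def test_climatology_single_year(self):
        annual = self._annual(np.stack([np.full((2, 2), 0.2), np.full((2, 2), 0.8)]))
        np.testing.assert_allclose(climatology_map(annual, (2000, 2000)).values, 0.2)

    def test_climatology_two_year_mean(self):
        annual = self._annual(np.stack([np.full((2, 2), 0.2), np.full((2, 2), 0.8)]))
        out = climatology_map(annual)
        np.testing.assert_allclose(out.values, 0.5)
        assert out.attrs["n_years"] == 2

    def test_climatology_empty_range_errors(self):
        annual = self._annual(np.full((2, 2, 2), 0.5))
        with pytest.raises(ValueError):
            climatology_map(annual, (1990, 1991))

    def test_climatology_skips_missing_years_per_cell(self):
        data = np.full((2, 2, 2), 0.4)
        data[0, 0, 0] = np.nan
        out = climatology_map(self._annual(data))
        assert out.values[0, 0] == pytest.approx(0.4)


class TestOnSyntheticGrid:
    def test_annual_k_in_unit_interval(self, annual_k):
        vals = annual_k.values
        assert np.nanmin(vals) >= 0 and np.nanmax(vals) <= 1

    def test_regional_series_contiguous_years(self, k_series):
        assert np.all(np.diff(k_series.years) == 1)
        assert np.all((k_series.values >= 0) & (k_series.values <= 1))
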
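"""Crop physiology responses, water balance and the rotation simulator."""

import math

import numpy as np
import pandas as pd
import pytest

from conftest import make_series
from rotaclim.crop_model import (
    CropParams,
    ManagementParams,
    SoilParams,
    co2_rue_modifier,
    co2_te_modifier,
    daily_thermal_time,
    load_default_params,
    photoperiod_factor,
    potential_et,
    simulate_crop,
    simulate_rotation,
    step_water_balance,
    vernalization_factor,
)
from rotaclim.weather_core import DailySeries


def _crop(**kw):
    base = dict(name="x", tbase=0.0, topt=26.0, tupper=34.0,
                tt_emerge=100.0, tt_flower=900.0, tt_grainfill=600.0)
    base.update(kw)
    return CropParams(**base)


class TestThermalTime:
    def test_zero_at_base_temperature(self):
        c = _crop()
        assert daily_thermal_time(0.0, 0.0, c) == 0.0

    def test_peak_at_optimum(self):
        c = _crop(tbase=0.0, topt=26.0, tupper=34.0)
        assert daily_thermal_time(26.0, 26.0, c) == pytest.approx(26.0)

    @pytest.mark.parametrize("tmean", [28.0, 30.0, 33.0])
    def test_linear_decline_between_optimum_and_upper(self, tmean):
        c = _crop(tbase=0.0, topt=26.0, tupper=34.0)
        expected = 26.0 * (34.0 - tmean) / (34.0 - 26.0)
        assert daily_thermal_time(tmean, tmean, c) == pytest.approx(expected)

    def test_zero_beyond_upper(self):
        c = _crop()
        assert daily_thermal_time(36.0, 34.0, c) == 0.0

    def test_cardinal_order_enforced(self):
        with pytest.raises(ValueError, match="cardinal"):
            _crop(tbase=30.0, topt=26.0)


class TestDevelopmentModifiers:
    def test_no_vernalization_requirement_means_unity(self):
        c = _crop(vern_days=0.0)
        assert vernalization_factor(0.0, c) == 1.0

    def test_saturated_vernalization(self):
        c = _crop(vern_days=30.0)
        assert vernalization_factor(45.0, c) == 1.0

    def test_linear_accrual_at_half_requirement(self):
        c = _crop(vern_days=30.0)
        assert vernalization_factor(15.0, c) == pytest.approx(0.5)

    def test_photoperiod_insensitive_crop(self):
        c = _crop(photoperiod_sens=0.0)
        assert photoperiod_factor(9.0, c) == 1.0

    def test_photoperiod_increases_with_day_length(self):
        c = _crop(photoperiod_sens=0.1, photoperiod_opt=14.0)
        f = [photoperiod_factor(h, c) for h in (9.0, 11.0, 13.0, 14.0, 15.0)]
        assert all(a <= b for a, b in zip(f, f[1:]))
        assert f[-1] == 1.0


class TestCO2Modifiers:
    def test_reference_normalization(self):
        c = _crop(co2_rue_slope=0.0007, co2_te_slope=0.0011)
        assert co2_rue_modifier(350.0, c) == 1.0
        assert co2_te_modifier(350.0, c) == 1.0

    def test_rue_doubling_response(self):
        c = _crop(co2_rue_slope=0.0007)
        assert co2_rue_modifier(700.0, c) == pytest.approx(1.245)

    def test_monotone_over_plausible_range(self):
        c = _crop(co2_rue_slope=0.0007, co2_te_slope=0.0011)
        grid = np.linspace(300, 1200, 60)
        rue = [co2_rue_modifier(x, c) for x in grid]
        te = [co2_te_modifier(x, c) for x in grid]
        assert all(a <= b for a, b in zip(rue, rue[1:]))
        assert all(a <= b for a, b in zip(te, te[1:]))

    def test_rue_cap_binds(self):
        c = _crop(co2_rue_slope=0.0007, rue_mod_cap=1.2)
        assert co2_rue_modifier(1200.0, c) == 1.2


class TestPotentialET:
    def test_zero_radiation_gives_zero(self):
        assert potential_et(0.0, 25.0, 15.0, 1.0) == 0.0

    def test_linear_in_radiation(self):
        a = potential_et(10.0, 25.0, 15.0, 1.0)
        b = potential_et(20.0, 25.0, 15.0, 1.0)
        assert b == pytest.approx(2 * a)

    def test_against_independent_priestley_taylor_oracle(self):
        # independent implementation: Magnus saturation pressure form
        tmean = 20.0
        es = 0.61094 * math.exp(17.625 * tmean / (tmean + 243.04))
        slope = es * 17.625 * 243.04 / (tmean + 243.04) ** 2
        oracle = 1.26 * slope / (slope + 0.066) * 0.75 * 15.0 / 2.45
        assert potential_et(15.0, 25.0, 15.0, 1.0) == pytest.approx(oracle, rel=0.02)


class TestWaterBalance:
    SOIL = SoilParams(capacity_mm=150.0, init_frac=0.8, soil_evap_coeff=1.0)

    def test_empty_soil_no_rain_gives_zero_et(self):
        s, aet, transp, drain, runoff = step_water_balance(0.0, 0.0, 0.0, 5.0, 0.5, self.SOIL)
        assert aet == 0.0 and transp == 0.0 and s == 0.0

    def test_saturated_soil_unstressed(self):
        s, aet, transp, _, _ = step_water_balance(150.0, 0.0, 0.0, 5.0, 0.5, self.SOIL)
        assert aet == pytest.approx(5.0)

    def test_mass_balance_closes_over_a_season(self, hefei):
        import rotaclim.synthetic_climate as sc

        meta, clim = hefei
        series = sc.generate_station_baseline(clim, meta, 1, seed=21)
        f = series.frame.iloc[120:240]  # ~120-day window
        storage = 100.0
        win = wout = 0.0
        s0 = storage
        for r in f.itertuples():
            pet = float(potential_et(r.rad, r.tmax, r.tmin, 1.0))
            storage, aet, _, drain, runoff = step_water_balance(
                storage, r.prec, 0.0, pet, 0.4, self.SOIL)
            win += r.prec
            wout += aet + drain + runoff
        assert abs(win - wout - (storage - s0)) < 1e-6

    def test_runoff_above_threshold(self):
        s, aet, _, drain, runoff = step_water_balance(100.0, 80.0, 0.0, 0.0, 0.0, self.SOIL)
        assert runoff >= 80.0 - self.SOIL.runoff_threshold_mm


@pytest.fixture(scope="module")
def rotation_weather(hefei):
    import rotaclim.synthetic_climate as sc

    meta, clim = hefei
    return sc.generate_station_baseline(clim, meta, 6, seed=31, start_year=1981)


@pytest.fixture(scope="module")
def co2_flat():
    return {y: 380.0 for y in range(1975, 2005)}


def _perturbed(series, dT=0.0, frad=1.0):
    f = series.frame.copy()
    f["tmax"] += dT
    f["tmin"] += dT
    f["rad"] *= frad
    return DailySeries(station=series.station, frame=f)


def _mean(results, crop, attr):
    vals = [getattr(r, attr) for r in results if r.crop == crop and not r.failed]
    return float(np.mean(vals))


def _mean_doy(results, crop, attr):
    vals = [getattr(r, attr).timetuple().tm_yday for r in results if r.crop == crop and not r.failed]
    return float(np.mean(vals))


class TestSimulateCrop:
    def test_zero_radiation_means_no_growth(self, default_params):
        wheat, rice, soil, mgmt = default_params
        s = make_series(start="2001-06-15", n=130, tmax=30.0, tmin=22.0, prec=4.0, rad=0.0)
        res = simulate_crop(s.frame, 380.0, rice, soil, irrigated=True, latitude=32.0)
        assert res.biomass_kg_ha == 0.0
        assert res.yield_kg_ha == 0.0

    def test_unreached_maturity_is_flagged_failed(self, default_params):
        wheat, _, soil, _ = default_params
        s = make_series(start="2001-10-15", n=60, tmax=12.0, tmin=4.0, prec=2.0, rad=9.0)
        res = simulate_crop(s.frame, 380.0, wheat, soil, latitude=32.0)
        assert res.failed
        assert res.maturity_date is None

    def test_water_balance_residuals_negligible(self, rotation_weather, co2_flat, default_params):
        wheat, rice, soil, mgmt = default_params
        results, _ = simulate_rotation(rotation_weather, co2_flat, wheat, rice, soil, mgmt)
        assert results, "no seasons simulated"
        assert max(abs(r.water_balance_residual_mm) for r in results) < 1e-6

    def test_warming_advances_wheat_phenology(self, rotation_weather, co2_flat, default_params):
        wheat, rice, soil, mgmt = default_params
        base, _ = simulate_rotation(rotation_weather, co2_flat, wheat, rice, soil, mgmt)
        warm, _ = simulate_rotation(_perturbed(rotation_weather, dT=2.0), co2_flat,
                                    wheat, rice, soil, mgmt)
        assert _mean_doy(warm, "wheat", "flowering_date") < _mean_doy(base, "wheat", "flowering_date")
        assert _mean_doy(warm, "wheat", "maturity_date") < _mean_doy(base, "wheat", "maturity_date")

    @pytest.mark.parametrize("crop", ["wheat", "rice"])
    def test_co2_raises_yield_and_lowers_et(self, rotation_weather, default_params, crop):
        wheat, rice, soil, mgmt = default_params
        lo, _ = simulate_rotation(rotation_weather, {y: 380.0 for y in range(1975, 2005)},
                                  wheat, rice, soil, mgmt)
        hi, _ = simulate_rotation(rotation_weather, {y: 550.0 for y in range(1975, 2005)},
                                  wheat, rice, soil, mgmt)
        assert _mean(hi, crop, "yield_kg_ha") > _mean(lo, crop, "yield_kg_ha")
        assert _mean(hi, crop, "et_mm") < _mean(lo, crop, "et_mm")

    @pytest.mark.parametrize("crop", ["wheat", "rice"])
    def test_extra_radiation_raises_yield_and_et(self, rotation_weather, co2_flat,
                                                 default_params, crop):
        wheat, rice, soil, mgmt = default_params
        base, _ = simulate_rotation(rotation_weather, co2_flat, wheat, rice, soil, mgmt)
        bright, _ = simulate_rotation(_perturbed(rotation_weather, frad=1.1), co2_flat,
                                      wheat, rice, soil, mgmt)
        assert _mean(bright, crop, "yield_kg_ha") > _mean(base, crop, "yield_kg_ha")
        assert _mean(bright, crop, "et_mm") > _mean(base, crop, "et_mm")

    def test_heat_stress_penalty_reduces_yield(self, rotation_weather, co2_flat, default_params):
        wheat, rice, soil, mgmt = default_params
        import dataclasses

        warm = _perturbed(rotation_weather, dT=3.0)
        with_pen, _ = simulate_rotation(warm, co2_flat, wheat, rice, soil, mgmt)
        no_pen_wheat = dataclasses.replace(wheat, heat_penalty=0.0)
        no_pen_rice = dataclasses.replace(rice, heat_penalty=0.0)
        without, _ = simulate_rotation(warm, co2_flat, no_pen_wheat, no_pen_rice, soil, mgmt)
        assert _mean(with_pen, "wheat", "yield_kg_ha") < _mean(without, "wheat", "yield_kg_ha")

    def test_rice_under_irrigation_rule_is_never_water_stressed(
        self, rotation_weather, co2_flat, default_params
    ):
        """Refill-to-saturation irrigation must equal an unlimited-supply run."""
        wheat, rice, soil, mgmt = default_params
        irr, _ = simulate_rotation(rotation_weather, co2_flat, wheat, rice, soil, mgmt)
        lush_soil = SoilParams(capacity_mm=100000.0, init_frac=1.0,
                               drainage_coeff=soil.drainage_coeff,
                               soil_evap_coeff=soil.soil_evap_coeff,
                               runoff_threshold_mm=1e9, uptake_coeff=1.0)
        free, _ = simulate_rotation(rotation_weather, co2_flat, wheat, rice, lush_soil, mgmt)
        assert _mean(irr, "rice", "yield_kg_ha") == pytest.approx(
            _mean(free, "rice", "yield_kg_ha"), rel=1e-9
        )

    def test_yield_biomass_and_wue_identities(self, rotation_weather, co2_flat, default_params):
        wheat, rice, soil, mgmt = default_params
        results, annual = simulate_rotation(rotation_weather, co2_flat, wheat, rice, soil, mgmt)
        for r in results:
            if r.failed:
                continue
            assert 0.0 <= r.yield_kg_ha <= r.biomass_kg_ha
            assert r.et_mm >= r.transpiration_mm >= 0.0
            assert r.wue * r.et_mm == pytest.approx(r.yield_kg_ha, abs=1e-6)


class TestRotation:
    def _cyclic_weather(self, years=4):
        """Deterministic annual cycle with periodic rain, repeated exactly."""
        doy = np.arange(365)
        tmax = 20.5 + 12.0 * np.cos(2 * np.pi * (doy - 197) / 365)
        tmin = tmax - 9.0
        rad = 12.5 + 5.5 * np.cos(2 * np.pi * (doy - 172) / 365)
        prec = np.where(doy % 4 == 0, 12.0, 0.0)
        frames = []
        for i in range(years):
            y = 2001 + i
            dates = pd.date_range(f"{y}-01-01", periods=365, freq="D")
            if len(dates) != 365 or dates[-1].dayofyear != 365:
                dates = pd.date_range(f"{y}-01-01", f"{y}-12-31", freq="D")
                sel = ~((dates.month == 2) & (dates.day == 29))
                dates = dates[sel]
            frames.append(pd.DataFrame({"date": dates, "tmax": tmax[: len(dates)],
                                        "tmin": tmin[: len(dates)], "prec": prec[: len(dates)],
                                        "rad": rad[: len(dates)]}))
        f = pd.concat(frames, ignore_index=True)
        # rebuild a strictly contiguous calendar (leap days filled by shift)
        f["date"] = pd.date_range("2001-01-01", periods=len(f), freq="D")
        from rotaclim.weather_core import StationMeta

        return DailySeries(station=StationMeta(station_id="cyc", latitude=32.0), frame=f)

    def test_steady_state_after_spinup(self, default_params):
        wheat, rice, soil, mgmt = default_params
        weather = self._cyclic_weather(5)
        co2 = {y: 400.0 for y in range(2000, 2010)}
        results, _ = simulate_rotation(weather, co2, wheat, rice, soil, mgmt)
        rice_seasons = [r for r in results if r.crop == "rice" and not r.failed]
        assert len(rice_seasons) >= 3
        a, b = rice_seasons[-2], rice_seasons[-1]
        assert a.yield_kg_ha == pytest.approx(b.yield_kg_ha, rel=5e-3)
        assert a.et_mm == pytest.approx(b.et_mm, rel=5e-3)

    def test_annual_totals_are_sums_of_the_two_crops(self, rotation_weather, co2_flat,
                                                     default_params):
        wheat, rice, soil, mgmt = default_params
        results, annual = simulate_rotation(rotation_weather, co2_flat, wheat, rice, soil, mgmt)
        by = {}
        for r in results:
            if not r.failed:
                by.setdefault(r.season, {})[r.crop] = r
        for row in annual.itertuples():
            d = by[row.year]
            assert row.yield_kg_ha == pytest.approx(
                d["wheat"].yield_kg_ha + d["rice"].yield_kg_ha, abs=1e-9
            )
            assert row.wue * row.et_mm == pytest.approx(row.yield_kg_ha, abs=1e-6)
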
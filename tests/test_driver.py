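"""End-to-end simulation: determinism, schedules, closures, scenarios."""

import numpy as np
import pandas as pd
import pytest

from pigemit.driver import annualize, annualize_outputs, run_growing_period, run_year
from pigemit.scenario import load_scenario, ls_preset, save_scenario, ss_preset
from pigemit.weather import weather_fixture


class TestWeatherFixture:
    def test_deterministic_for_same_seed(self):
        a = weather_fixture(42, n_days=100)
        b = weather_fixture(42, n_days=100)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_differs(self):
        a = weather_fixture(42, n_days=100)
        b = weather_fixture(43, n_days=100)
        assert not np.allclose(a.T_out_C, b.T_out_C)

    def test_no_cycle_no_noise_is_constant(self):
        w = weather_fixture(0, n_days=50, amplitude_T=0.0, sigma_T=0.0)
        assert np.allclose(w.T_out_C, 10.5)

    def test_annual_mean_near_climate_normal(self):
        w = weather_fixture(5, n_days=365)
        assert w.T_out_C.mean() == pytest.approx(10.5, abs=0.5)

    def test_summer_warmer_than_winter(self):
        w = weather_fixture(5, n_days=365, sigma_T=0.0)
        doy = (281 + np.arange(365)) % 365
        summer = w.T_out_C[np.isin(doy // 30, [6, 7])].mean()  # Jul/Aug-ish
        winter = w.T_out_C[np.isin(doy // 30, [0, 1])].mean()
        assert summer > winter + 5.0


class TestGrowingPeriod:
    def test_deterministic_end_to_end(self, ls_scenario, fixture_weather):
        a = run_growing_period(ls_scenario, fixture_weather)
        b = run_growing_period(ls_scenario, fixture_weather)
        pd.testing.assert_frame_equal(a.daily, b.daily)

    def test_zero_headcount_emits_nothing(self, fixture_weather):
        sc = ls_preset(n_places=0)
        res = run_growing_period(sc, fixture_weather)
        for col in ("nh3_total_kg", "ch4_total_kg"):
            assert np.allclose(res.daily[col], 0.0)

    def test_removal_days_drop_pit_volume(self, ls_scenario, fixture_weather):
        res = run_growing_period(ls_scenario, fixture_weather)
        d = res.daily
        assert d.loc[d.day_of_gp == 45, "removed_volume_m3"].iloc[0] > 0
        assert d.loc[d.day_of_gp == 90, "removed_volume_m3"].iloc[0] > 0
        assert d.loc[d.day_of_gp == 44, "removed_volume_m3"].iloc[0] == 0
        # emission sawtooth: CH4 right after emptying below the day before
        ch4 = d.ch4_pit_kg.to_numpy()
        assert ch4[45] < ch4[44]
        assert ch4[90] < ch4[89]

    def test_weight_series_spans_growth_range(self, ls_scenario, fixture_weather):
        res = run_growing_period(ls_scenario, fixture_weather)
        w = res.daily.weight_kg
        assert w.iloc[-1] == pytest.approx(115.6, rel=1e-6)
        assert w.is_monotonic_increasing

    def test_insufficient_weather_raises(self, ls_scenario):
        short = weather_fixture(1, n_days=10)
        with pytest.raises(ValueError, match="weather"):
            run_growing_period(ls_scenario, short)


@pytest.fixture(scope="module")
def ls_year(ls_scenario, fixture_weather):
    return run_year(ls_scenario, fixture_weather)


@pytest.fixture(scope="module")
def ss_year(ss_scenario, fixture_weather):
    return run_year(ss_scenario, fixture_weather)


class TestYear:
    def test_mass_closure_volume_vs_tan(self, ls_year, ss_year):
        for res in (ls_year, ss_year):
            led, fin = res.ledger, res.final_storage()
            assert led.volume_in == pytest.approx(
                led.volume_removed + fin["volume"], rel=1e-6
            )
            assert led.vs_in == pytest.approx(
                led.vs_removed + led.vs_degraded + fin["VS"], rel=1e-6
            )
            assert led.tan_in == pytest.approx(
                led.tan_removed + led.tan_volatilized + fin["TAN"], rel=1e-6
            )

    def test_short_storage_cuts_both_gases(self, ls_year, ss_year):
        ls, ss = annualize_outputs(ls_year), annualize_outputs(ss_year)
        assert ss["ch4_total_kg_yr_place"] < ls["ch4_total_kg_yr_place"]
        assert ss["nh3_total_kg_yr_place"] < ls["nh3_total_kg_yr_place"]

    def test_vacancy_days_have_no_pigs_but_pit_still_emits(self, ls_year):
        vac = ls_year.daily[ls_year.daily.gp == -1]
        assert (vac.headcount == 0).all()
        assert (vac.feed_kg == 0).all()
        assert vac.ch4_pit_kg.gt(0).all()

    def test_annualized_magnitudes_plausible(self, ls_year, ss_year):
        # annual levels within the plausibility bands of Dutch fattening
        # rooms: LS CH4 of order 10-25, SS a few kg; NH3 of order 1-5
        ls, ss = annualize_outputs(ls_year), annualize_outputs(ss_year)
        assert 8.0 < ls["ch4_total_kg_yr_place"] < 30.0
        assert 1.5 < ss["ch4_total_kg_yr_place"] < 10.0
        assert 1.0 < ls["nh3_total_kg_yr_place"] < 6.0
        assert 0.3 < ss["nh3_total_kg_yr_place"] < 4.0


class TestAnnualize:
    def test_arithmetic(self):
        series = np.full(100, 0.1)
        assert annualize(series, 50, vacancy=0.0) == pytest.approx(0.73)

    def test_vacancy_scaling_exact(self):
        series = np.full(10, 0.2)
        assert annualize(series, 50, vacancy=0.03) == pytest.approx(
            0.97 * annualize(series, 50, vacancy=0.0), rel=1e-12
        )

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            annualize(np.array([]), 50)


class TestScenarioConfig:
    def test_yaml_round_trip(self, tmp_path, ss_scenario):
        path = tmp_path / "ss.yaml"
        save_scenario(ss_scenario, path)
        loaded = load_scenario(path)
        assert loaded == ss_scenario

    def test_round_trip_simulates_identically(self, tmp_path, ls_scenario):
        path = tmp_path / "ls.yaml"
        save_scenario(ls_scenario, path)
        loaded = load_scenario(path)
        wx = weather_fixture(3, n_days=120)
        a = run_growing_period(ls_scenario, wx)
        b = run_growing_period(loaded, wx)
        pd.testing.assert_frame_equal(a.daily, b.daily)

    def test_validation_errors_name_the_field(self):
        with pytest.raises(ValueError, match="manure_fraction"):
            ss_preset().channels[0].__class__(
                name="bad",
                geometry=ss_preset().channels[0].geometry,
                schedule=ss_preset().channels[0].schedule,
                manure_fraction=1.5,
            )
        with pytest.raises(ValueError, match="slatted_frac"):
            ls_preset(slatted_frac=1.2)

    def test_channel_fractions_must_sum_to_one(self, ss_scenario):
        bad = [c for c in ss_scenario.channels]
        from dataclasses import replace

        bad[0] = replace(bad[0], manure_fraction=0.5)
        with pytest.raises(ValueError, match="sum to 1"):
            ss_scenario.replace(channels=tuple(bad))
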
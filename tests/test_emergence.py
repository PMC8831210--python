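"""Cue calibration and emergence prediction: quantile conventions,
first-crossing scans, and the four cue models against brute force."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from phenotrap.emergence import (
    CueConfig,
    calibrate_threshold,
    predict_emergence,
    predict_emergence_air,
    predict_emergence_gradient_collapse,
    predict_emergence_sharp_rise,
    run_emergence_stage,
    sighting_degree_hours,
)
from phenotrap.microclimate import (
    OMEGA_ANNUAL,
    ClimateParams,
    SightingGenParams,
    SiteConfig,
    generate_sightings,
    simulate_temperature_series,
)
from phenotrap.pipeline import build_degree_hour_store
from phenotrap.series import SOIL_10, SOIL_50, SURFACE, SeriesStore, TemperatureSeries
from phenotrap.thermal import accumulate_degree_hours
from tests.conftest import constant_year, seeded_year


class TestCalibrateThreshold:
    def test_constant_values_give_that_constant(self):
        for p in (0.025, 0.05, 0.10):
            assert calibrate_threshold([42.0] * 9, p).value == 42.0

    def test_linear_interpolation_between_order_statistics(self):
        # type-7 rule on {10, 20, ..., 200}: h = (20-1)*0.05 = 0.95, so the
        # 5th percentile interpolates 0.95 of the way from 10 to 20
        values = np.arange(10.0, 201.0, 10.0)
        thr = calibrate_threshold(values, 0.05)
        assert thr.value == pytest.approx(19.5)
        # independent oracle: numpy's default quantile is the same rule
        assert thr.value == pytest.approx(float(np.quantile(values, 0.05)))

    @given(
        st.lists(st.floats(0.0, 1e4), min_size=1, max_size=40),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_percentile(self, values):
        lo = calibrate_threshold(values, 0.025).value
        mid = calibrate_threshold(values, 0.05).value
        hi = calibrate_threshold(values, 0.10).value
        assert lo <= mid <= hi

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            calibrate_threshold([], 0.05)


class TestSightingDegreeHours:
    def test_sighting_at_accumulation_start_is_zero(self):
        s = constant_year(9.0)
        dh = accumulate_degree_hours(s, 7.0)
        out = sighting_degree_hours(
            pd.DataFrame({"site_id": ["s1"], "date": [pd.Timestamp(2000, 1, 1)]}),
            {("s1", 2000): dh},
        )
        assert out["value"].iloc[0] == 0.0

    def test_constant_nine_next_day_is_48(self):
        # 24 h at 2 degC above base before Jan 2 00:00
        s = constant_year(9.0)
        dh = accumulate_degree_hours(s, 7.0)
        out = sighting_degree_hours(
            pd.DataFrame({"site_id": ["s1"], "date": [pd.Timestamp(2000, 1, 2)]}),
            {("s1", 2000): dh},
        )
        assert out["value"].iloc[0] == pytest.approx(48.0)

    def test_matches_per_sighting_brute_force(self):
        s = seeded_year(31, mean=6.0, amp=8.0, noise=2.0)
        dh = accumulate_degree_hours(s, 7.0)
        rng = np.random.default_rng(8)
        days = rng.integers(1, 150, 50)
        dates = [pd.Timestamp(2000, 1, 1) + pd.Timedelta(days=int(d)) for d in days]
        out = sighting_degree_hours(
            pd.DataFrame({"site_id": "s1", "date": dates}), {("s1", 2000): dh}
        )
        temps = s.data
        for date, value in zip(out["date"], out["value"]):
            brute = sum(
                max(v - 7.0, 0.0) for t, v in temps.items() if t < date
            )
            assert value == pytest.approx(brute, abs=1e-9)

    def test_missing_series_skipped(self):
        out = sighting_degree_hours(
            pd.DataFrame({"site_id": ["nope"], "date": [pd.Timestamp(2000, 2, 1)]}),
            {},
        )
        assert len(out) == 0


class TestPredictEmergence:
    def test_constant_ten_reaches_21_at_hour_seven(self):
        dh = accumulate_degree_hours(constant_year(10.0), 7.0)
        pred = predict_emergence(dh, 21.0)
        assert pred.emergence_time == pd.Timestamp(2000, 1, 1, 7)
        assert pred.dh_at_emergence == pytest.approx(21.0)

    def test_never_reached_is_absent(self):
        dh = accumulate_degree_hours(constant_year(5.0), 7.0)
        pred = predict_emergence(dh, 21.0)
        assert not pred.emerged
        assert pd.isna(pred.emergence_time)

    def test_matches_brute_force_first_crossing(self):
        dh = accumulate_degree_hours(seeded_year(17), 7.0)
        pred = predict_emergence(dh, 21.0)
        window = dh.data.loc[pd.Timestamp(2000, 1, 1) : pd.Timestamp(2000, 5, 31, 23)]
        brute = next(t for t, v in window.items() if v >= 21.0)
        assert pred.emergence_time == brute

    def test_crossing_property_holds(self):
        dh = accumulate_degree_hours(seeded_year(23), 7.0)
        pred = predict_emergence(dh, 50.0)
        before = dh.data.loc[pred.emergence_time - pd.Timedelta(hours=1)]
        assert before < 50.0 <= pred.dh_at_emergence

    def test_emergence_date_monotone_in_threshold(self):
        dh = accumulate_degree_hours(seeded_year(29), 7.0)
        times = [
            predict_emergence(dh, thr).emergence_time for thr in (10.0, 21.0, 80.0)
        ]
        assert times[0] <= times[1] <= times[2]


class TestGradientCollapse:
    def test_shallow_always_colder_is_absent(self):
        t10 = constant_year(4.0, level=SOIL_10)
        t50 = constant_year(6.0, level=SOIL_50)
        assert not predict_emergence_gradient_collapse(t10, t50).emerged

    def test_step_reversal_fires_on_that_day(self):
        idx = pd.date_range("2000-01-01", "2000-12-31 23:00", freq="h")
        deep = pd.Series(5.0, index=idx)
        shallow = pd.Series(4.9, index=idx)
        flip = pd.Timestamp(2000, 3, 15)
        shallow.loc[flip:] = 5.1
        pred = predict_emergence_gradient_collapse(
            TemperatureSeries("s1", SOIL_10, shallow),
            TemperatureSeries("s1", SOIL_50, deep),
        )
        assert pred.emergence_time == flip

    def test_matches_closed_form_crossing_of_damped_harmonics(self):
        # noise-free profiles: the daily means cross where the two damped
        # annual sinusoids are equal; solve that instant independently
        p = ClimateParams(
            mean_temp=8.0,
            annual_amplitude=7.0,
            diurnal_amplitude=3.0,
            warming_rate=0.0,
            noise_sd=0.0,
            damping_depth_annual=1.0,
        )
        site = SiteConfig("cf", 50.0, -5.0, False, p)
        t10 = simulate_temperature_series(site, SOIL_10, (2000, 2000), 0)
        t50 = simulate_temperature_series(site, SOIL_50, (2000, 2000), 0)
        pred = predict_emergence_gradient_collapse(t10, t50)

        def diff(t_hours):
            a = 7.0 * np.exp(-0.1) * np.sin(
                OMEGA_ANNUAL * t_hours + p.annual_phase - 0.1
            )
            b = 7.0 * np.exp(-0.5) * np.sin(
                OMEGA_ANNUAL * t_hours + p.annual_phase - 0.5
            )
            return a - b

        root_h = brentq(diff, 24 * 30, 24 * 150)
        expected_day = pd.Timestamp(2000, 1, 1) + pd.Timedelta(hours=root_h)
        assert abs(pred.emergence_time - expected_day.normalize()) <= pd.Timedelta(
            days=1
        )


class TestAirCue:
    def test_constant_above_threshold_fires_when_window_defined(self):
        air = constant_year(12.0, level="air")
        pred = predict_emergence_air(air, CueConfig(cue="air_rolling_mean"))
        assert pred.emergence_time == air.timestamps[240 - 1]

    def test_constant_below_threshold_is_absent(self):
        air = constant_year(9.0, level="air")
        assert not predict_emergence_air(air, CueConfig(cue="air_rolling_mean")).emerged

    def test_step_series_matches_brute_force(self):
        idx = pd.date_range("2000-01-01", "2000-12-31 23:00", freq="h")
        temps = pd.Series(5.0, index=idx)
        temps.iloc[2000:] = 15.0
        air = TemperatureSeries("s1", "air", temps)
        cfg = CueConfig(cue="air_rolling_mean", air_window=240, air_threshold=10.0)
        pred = predict_emergence_air(air, cfg)
        arr = temps.to_numpy()
        brute = next(
            i
            for i in range(239, len(arr))
            if arr[i - 239 : i + 1].mean() >= 10.0
        )
        assert pred.emergence_time == idx[brute]


class TestSharpRise:
    def test_single_pulse_fires_at_pulse_end(self):
        idx = pd.date_range("2000-01-01", "2000-12-31 23:00", freq="h")
        temps = pd.Series(0.0, index=idx)
        pulse_start, pulse_end = 1800, 1880
        temps.iloc[pulse_start:pulse_end] = 12.0
        dh = accumulate_degree_hours(TemperatureSeries("s1", "surface", temps), 7.0)
        pred = predict_emergence_sharp_rise(dh, 240)
        assert pred.emergence_time == idx[pulse_end]

    def test_constant_rate_breaks_tie_to_earliest(self):
        dh = accumulate_degree_hours(constant_year(9.0), 7.0)
        pred = predict_emergence_sharp_rise(dh, 240)
        assert pred.emergence_time == dh.timestamps[240]

    def test_no_accumulation_is_absent(self):
        dh = accumulate_degree_hours(constant_year(3.0), 7.0)
        assert not predict_emergence_sharp_rise(dh, 240).emerged

    def test_matches_exhaustive_scan(self):
        dh = accumulate_degree_hours(seeded_year(41), 7.0)
        w = 240
        pred = predict_emergence_sharp_rise(dh, w)
        window = dh.data.loc[pd.Timestamp(2000, 1, 1) : pd.Timestamp(2000, 5, 31, 23)]
        v = window.to_numpy()
        gains = [(v[i] - v[i - w], i) for i in range(w, len(v))]
        best_gain = max(g for g, _ in gains)
        best_i = next(i for g, i in gains if g == best_gain)
        assert pred.emergence_time == window.index[best_i]


@pytest.fixture(scope="module")
def flat_world():
    """Three constant-9-degC sites: the threshold is attainable exactly
    at a midnight, so zero-lag calibration is exact."""
    p = ClimateParams(
        mean_temp=9.0,
        annual_amplitude=0.0,
        diurnal_amplitude=0.0,
        warming_rate=0.0,
        noise_sd=0.0,
    )
    sites = [SiteConfig(f"s{i}", 50.0, -5.0, False, p) for i in range(3)]
    store = SeriesStore()
    for s in sites:
        for lv in (SURFACE, SOIL_10, SOIL_50):
            store.add(simulate_temperature_series(s, lv, (2000, 2004), 1))
    return sites, store


class TestRunEmergenceStage:
    def test_zero_lag_recovers_generating_threshold_exactly(self, flat_world):
        sites, store = flat_world
        gen = SightingGenParams(
            true_threshold=96.0,
            lag_distribution="zero",
            sightings_per_year=6,
            years=(2000, 2004),
            seed=2,
        )
        sightings, _ = generate_sightings(sites, gen, store)
        dh_store = build_degree_hour_store(store, 7.0)
        thr, preds = run_emergence_stage(sightings, dh_store, CueConfig())
        assert thr.value == pytest.approx(96.0)
        assert len(preds) == len(dh_store)

    def test_lagged_calibration_bounds_truth_from_above(self, flat_world):
        sites, store = flat_world
        gen = SightingGenParams(
            true_threshold=96.0,
            lag_distribution="uniform",
            lag_days=5.0,
            sightings_per_year=20,
            years=(2000, 2004),
            seed=3,
        )
        sightings, _ = generate_sightings(sites, gen, store)
        dh_store = build_degree_hour_store(store, 7.0)
        thr, _ = run_emergence_stage(sightings, dh_store, CueConfig())
        # each lag day adds 48 degC h in this constant world
        assert 96.0 <= thr.value <= 96.0 + 5 * 48.0

    def test_lower_percentile_gives_earlier_or_equal_dates(self, flat_world):
        sites, store = flat_world
        gen = SightingGenParams(
            true_threshold=96.0,
            lag_distribution="uniform",
            lag_days=5.0,
            sightings_per_year=20,
            years=(2000, 2004),
            seed=4,
        )
        sightings, _ = generate_sightings(sites, gen, store)
        dh_store = build_degree_hour_store(store, 7.0)
        _, preds_05 = run_emergence_stage(
            sightings, dh_store, CueConfig(percentile=0.05)
        )
        _, preds_025 = run_emergence_stage(
            sightings, dh_store, CueConfig(percentile=0.025)
        )
        for a, b in zip(preds_025, preds_05):
            assert a.emergence_time <= b.emergence_time

    def test_no_sightings_is_hard_error(self, flat_world):
        _, store = flat_world
        dh_store = build_degree_hour_store(store, 7.0)
        with pytest.raises(ValueError):
            run_emergence_stage(pd.DataFrame(columns=["site_id", "date"]), dh_store)
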
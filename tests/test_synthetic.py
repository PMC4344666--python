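import numpy as np
import pandas as pd
import pytest

import thermomort as tm
from thermomort.preprocessing import apparent_temperature
from thermomort.synthetic import (
    TruthRanges,
    generate_daily_series,
    generate_regions,
    generate_scenario,
    seasonal_temperature,
    simulate_event_observations,
)
from thermomort.scenario import compute_threshold
from .conftest import flat_truth


def test_generate_regions_deterministic():
    a = generate_regions(2, seed=7)
    b = generate_regions(2, seed=7)
    for ta, tb in zip(a, b):
        assert ta.to_dict() == tb.to_dict()


def test_generate_regions_linear_only_gives_v_shape():
    ranges = TruthRanges(
        warm_beta2=(0.0, 0.0), warm_beta3=(0.0, 0.0),
        cold_beta2=(0.0, 0.0), cold_beta3=(0.0, 0.0),
    )
    (truth,) = generate_regions(1, seed=3, ranges=ranges)
    x = np.arange(truth.comfort_temp - 30, truth.comfort_temp + 20, 0.1)
    y = truth.log_rate(x)
    xmin = x[np.argmin(y)]
    assert abs(xmin - truth.comfort_temp) < 0.1001


def test_truth_curves_monotone_on_each_tail():
    # grid-evaluation oracle over the full generated range, 0.1 degC steps
    for truth in generate_regions(54, seed=5):
        xw = np.arange(truth.comfort_temp, truth.comfort_temp + 25, 0.1)
        yw = truth.log_rate(xw)
        assert (np.diff(yw) >= -1e-9).all(), truth.region_id
        xc = np.arange(truth.comfort_temp - 35, truth.comfort_temp, 0.1)
        yc = truth.log_rate(xc)
        assert (np.diff(yc) <= 1e-9).all(), truth.region_id


def test_truth_curve_continuous_at_comfort():
    for truth in generate_regions(10, seed=9):
        assert truth.intercept_warm == truth.intercept_cold
        eps = 1e-9
        below = truth.log_rate(truth.comfort_temp - eps)
        at = truth.log_rate(truth.comfort_temp)
        assert abs(below - at) < 1e-6


def test_unsatisfiable_monotonicity_fails_with_region_index():
    ranges = TruthRanges(cold_beta3=(0.01, 0.01))  # always convex-up blowup
    with pytest.raises(RuntimeError, match="region index 0"):
        generate_regions(1, seed=0, ranges=ranges)


@pytest.mark.parametrize(
    "start, n_years, expected_days",
    [("1998-01-01", 6, 2191), ("1999-01-01", 1, 365), ("2000-01-01", 1, 366)],
)
def test_daily_series_calendar_length(start, n_years, expected_days):
    truth = flat_truth()
    series = generate_daily_series(truth, start_date=start, n_years=n_years, seed=1)
    assert len(series) == expected_days


def test_daily_series_seed_determinism():
    truth = generate_regions(1, seed=4)[0]
    a = generate_daily_series(truth, n_years=2, seed=42)
    b = generate_daily_series(truth, n_years=2, seed=42)
    pd.testing.assert_frame_equal(a.to_frame(), b.to_frame())
    c = generate_daily_series(truth, n_years=2, seed=43)
    assert not np.array_equal(a.deaths, c.deaths)


def test_degenerate_noise_gives_constant_rate():
    truth = flat_truth(sigma=0.0, temp_noise_sd=0.0)
    series = generate_daily_series(truth, n_years=1, seed=0)
    expected = np.rint(np.exp(truth.intercept_warm) * truth.population / 1e6)
    np.testing.assert_array_equal(series.deaths, np.full(len(series), expected))
    assert np.ptp(series.rate) == 0.0


def test_generated_tapp_reproducible_from_raw_columns():
    # preprocessing applied to the back-filled air/dew columns must return
    # the generated apparent temperature exactly (up to 1e-9 degC)
    truth = flat_truth(temp_noise_sd=0.0)
    series = generate_daily_series(truth, n_years=1, seed=0)
    expected = seasonal_temperature(
        series.dates, truth.temp_mean, truth.temp_amplitude
    )
    recomputed = apparent_temperature(series.tair, series.tdewpt)
    np.testing.assert_allclose(recomputed, expected, atol=1e-9)
    np.testing.assert_allclose(series.tapp, expected, atol=1e-9)


def test_poisson_mode_mean_matches_truth():
    truth = flat_truth(population=2e6)
    n_years = 28  # > 10^4 simulated days
    series = generate_daily_series(
        truth, n_years=n_years, seed=8, noise_mode="poisson_count"
    )
    lam = np.exp(truth.intercept_warm) * truth.population / 1e6
    se = np.sqrt(lam / len(series))
    assert abs(series.deaths.mean() - lam) < 3 * se


def test_scenario_shapes_and_tail_membership():
    truths = generate_regions(5, seed=2)
    scen = generate_scenario(truths, kind="heatwave", n_days=15, seed=0,
                             severity=8.0, noise_sd=0.0)
    assert len(scen) == 5 * 15
    for truth in truths:
        t = scen.loc[scen["region_id"] == truth.region_id, "tapp_c"]
        assert (t >= truth.comfort_temp).all()
        assert np.allclose(t, truth.comfort_temp + 8.0)
    cold = generate_scenario(truths, kind="coldspell", n_days=15, seed=0,
                             severity=10.0)
    for truth in truths:
        t = cold.loc[cold["region_id"] == truth.region_id, "tapp_c"]
        assert (t < truth.comfort_temp).all()


def test_scenario_deterministic():
    truths = generate_regions(3, seed=2)
    a = generate_scenario(truths, kind="heatwave", seed=5)
    b = generate_scenario(truths, kind="heatwave", seed=5)
    pd.testing.assert_frame_equal(a, b)


def test_severe_coldspell_exceeds_analytic_threshold_for_steep_tail():
    # steep cold tail, noise-free: the episode's true event-mean rate must
    # exceed the cold-tail 75th-percentile threshold of the observed series
    truth = tm.RegionTruth(
        region_id="STEEP",
        population=5e6,
        comfort_temp=20.0,
        intercept_warm=np.log(25.0),
        intercept_cold=np.log(25.0),
        coef_warm=np.array([0.02, 0.002, 0.0]),
        coef_cold=np.array([-0.025, 0.001, 0.0]),
        sigma_warm=0.0,
        sigma_cold=0.0,
        temp_mean=16.0,
        temp_amplitude=11.0,
        temp_noise_sd=2.0,
    )
    series = generate_daily_series(truth, n_years=6, seed=1)
    comfort = tm.ComfortTemperature(region_id="STEEP", x_im=20.0, interval_index=0)
    thr = compute_threshold(series, comfort, "cold", level=0.75)
    x_event = truth.comfort_temp - 20.0 - 5.0  # severity 20 + seasonal offset 5
    event_mean_true = float(np.exp(truth.log_rate(x_event)))
    assert event_mean_true > thr.value


def test_event_observations_follow_truth_curve():
    truths = [flat_truth(sigma=0.0)]
    scen = generate_scenario(truths, kind="heatwave", seed=0, noise_sd=0.0)
    obs = simulate_event_observations(truths, scen, seed=0)
    expected = np.rint(np.exp(truths[0].intercept_warm) * truths[0].population / 1e6)
    expected_rate = expected / truths[0].population * 1e6
    np.testing.assert_allclose(obs["obs_rate"], expected_rate)
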
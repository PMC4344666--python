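import numpy as np
import pandas as pd
import pytest

from thermomort.curves import ComfortTemperature
from thermomort.model import PosteriorDraws
from thermomort.scenario import (
    EmergencyThreshold,
    ScenarioResult,
    compute_threshold,
    exceedance_probability,
    simulate_scenario,
)
from .conftest import make_series


def comfort(x_im=20.0, region_id="T"):
    return ComfortTemperature(region_id=region_id, x_im=x_im, interval_index=0)


def degenerate_draws(tail, alpha, n=1000, sigma=1e-12, centering=20.0,
                     region_id="T", beta=(0.0, 0.0, 0.0)):
    ones = np.ones(n)
    return PosteriorDraws(
        region_id=region_id, tail=tail,
        alpha=alpha * ones,
        beta1=beta[0] * ones, beta2=beta[1] * ones, beta3=beta[2] * ones,
        sigma=sigma * ones, centering=centering, seed=0,
    )


class TestComputeThreshold:
    def test_quantile_interpolation_oracle(self):
        series = make_series([25.0, 26.0, 27.0, 28.0], [1.0, 2.0, 3.0, 4.0])
        thr = compute_threshold(series, comfort(), "warm", level=0.75)
        assert thr.value == pytest.approx(3.25)  # (n-1)*q order-statistic rule

    def test_constant_rates_any_level(self):
        series = make_series([25.0] * 6, [7.0] * 6)
        for level in (0.1, 0.5, 0.75, 0.9):
            assert compute_threshold(series, comfort(), "warm", level).value == 7.0

    def test_empty_or_sparse_tail_fails(self):
        series = make_series([25.0] * 6, [7.0] * 6)  # all warm
        with pytest.raises(ValueError, match="no days in the cold"):
            compute_threshold(series, comfort(), "cold")
        sparse = make_series([25.0, 25.0, 15.0, 15.0, 15.0, 15.0],
                             [1.0] * 6)
        with pytest.raises(ValueError, match="warm"):
            compute_threshold(sparse, comfort(), "warm")

    def test_tail_conditioning_boundary_day_is_warm(self):
        series = make_series([20.0, 19.9, 25.0, 25.0, 25.0, 15.0, 15.0, 15.0],
                             [9.0, 1.0, 9.0, 9.0, 9.0, 1.0, 1.0, 1.0])
        thr = compute_threshold(series, comfort(20.0), "warm", level=0.5)
        assert thr.value == 9.0  # the tapp == x_im day counts as warm


class TestSimulateScenario:
    def test_degenerate_posterior_constant_event_mean(self):
        dw = degenerate_draws("warm", alpha=np.log(30.0))
        dc = degenerate_draws("cold", alpha=np.log(50.0))
        x = np.full(15, 20.0)  # at the centering temperature
        res = simulate_scenario(dw, dc, comfort(), x, seed=1)
        np.testing.assert_allclose(res.event_mean_draws, 30.0, rtol=1e-9)

    def test_day_at_comfort_routes_warm(self):
        dw = degenerate_draws("warm", alpha=np.log(2.0))
        dc = degenerate_draws("cold", alpha=np.log(3.0))
        res = simulate_scenario(dw, dc, comfort(20.0), np.array([20.0]), seed=0)
        np.testing.assert_allclose(res.event_mean_draws, 2.0, rtol=1e-9)
        below = simulate_scenario(dw, dc, comfort(20.0), np.array([19.999]), seed=0)
        np.testing.assert_allclose(below.event_mean_draws, 3.0, rtol=1e-9)

    def test_single_day_event_mean_is_daily_rate(self):
        dw = degenerate_draws("warm", alpha=np.log(30.0), sigma=0.2)
        dc = degenerate_draws("cold", alpha=np.log(30.0), sigma=0.2)
        res = simulate_scenario(dw, dc, comfort(), np.array([25.0]), seed=3)
        np.testing.assert_allclose(
            res.event_mean_draws, np.exp(res.daily_draws[:, 0]), rtol=1e-12
        )

    def test_seed_determinism(self):
        dw = degenerate_draws("warm", alpha=3.0, sigma=0.1)
        dc = degenerate_draws("cold", alpha=3.0, sigma=0.1)
        x = np.full(15, 24.0)
        a = simulate_scenario(dw, dc, comfort(), x, seed=5)
        b = simulate_scenario(dw, dc, comfort(), x, seed=5)
        np.testing.assert_array_equal(a.daily_draws, b.daily_draws)

    def test_mismatched_sample_counts_fail(self):
        dw = degenerate_draws("warm", alpha=3.0, n=100)
        dc = degenerate_draws("cold", alpha=3.0, n=99)
        with pytest.raises(ValueError, match="mismatch"):
            simulate_scenario(dw, dc, comfort(), np.array([25.0]), seed=0)
        with pytest.raises(ValueError, match="no days"):
            simulate_scenario(
                degenerate_draws("warm", 3.0), degenerate_draws("cold", 3.0),
                comfort(), np.array([]), seed=0,
            )

    def test_event_mean_obeys_jensen_per_draw(self):
        dw = degenerate_draws("warm", alpha=3.4, sigma=0.3, beta=(0.02, 0.001, 0.0))
        dc = degenerate_draws("cold", alpha=3.4, sigma=0.3, beta=(-0.02, 0.001, 0.0))
        rng = np.random.default_rng(7)
        x = rng.uniform(10.0, 30.0, 15)
        res = simulate_scenario(dw, dc, comfort(), x, seed=2)
        lhs = res.event_mean_draws
        rhs = np.exp(res.daily_draws.mean(axis=1))
        assert (lhs >= rhs - 1e-12).all()


def make_result(event_means, region_id="T"):
    event_means = np.asarray(event_means, dtype=float)
    n = len(event_means)
    return ScenarioResult(
        region_id=region_id,
        dates=pd.date_range("2003-08-01", periods=1),
        x_it=np.array([28.0]),
        daily_draws=np.log(event_means)[:, None],
        event_mean_draws=event_means,
    )


class TestExceedance:
    def test_counting(self):
        res = make_result(np.r_[np.full(700, 11.0), np.full(300, 9.0)])
        thr = EmergencyThreshold("T", "warm", 0.75, 10.0)
        assert exceedance_probability(res, thr) == pytest.approx(0.70)
        assert exceedance_probability(
            make_result([11.0, 12.0]), thr
        ) == 1.0
        assert exceedance_probability(make_result([1.0, 2.0]), thr) == 0.0

    def test_strict_inequality_at_threshold(self):
        res = make_result([10.0, 10.0, 12.0, 8.0])
        thr = EmergencyThreshold("T", "warm", 0.75, 10.0)
        assert exceedance_probability(res, thr) == pytest.approx(0.25)

    def test_observed_outcome_recorded(self):
        res = make_result([11.0, 9.0])
        thr = EmergencyThreshold("T", "warm", 0.75, 10.0)
        exceedance_probability(res, thr, observed_event_mean=10.5)
        assert res.observed_exceeds is True
        exceedance_probability(res, thr, observed_event_mean=10.0)
        assert res.observed_exceeds is False  # strict comparison for ties

    def test_monotone_nonincreasing_in_threshold_value(self):
        rng = np.random.default_rng(1)
        res = make_result(np.exp(rng.normal(3.0, 0.4, 1000)))
        values = np.linspace(5.0, 60.0, 40)
        probs = [
            exceedance_probability(
                res, EmergencyThreshold("T", "warm", 0.75, float(v))
            )
            for v in values
        ]
        assert (np.diff(probs) <= 1e-12).all()

    def test_empty_draws_fail(self):
        res = make_result([11.0])
        res.event_mean_draws = np.array([])
        with pytest.raises(ValueError, match="no draws"):
            exceedance_probability(res, EmergencyThreshold("T", "warm", 0.75, 1.0))


def test_exceedance_probabilities_are_calibrated():
    """Reliability: when forecasts come from the true generative model, the
    observed exceedance frequency in each forecast-probability bin must match
    the bin's mean forecast probability within binomial error.

    The posterior is taken degenerate at the truth so the check isolates the
    simulation/threshold machinery from estimation error.
    """
    rng = np.random.default_rng(2024)
    n_regions, n_draws, n_days = 300, 400, 15
    probs, outcomes = [], []
    for i in range(n_regions):
        alpha = rng.uniform(3.0, 3.6)
        sigma = rng.uniform(0.05, 0.15)
        dw = degenerate_draws("warm", alpha=alpha, sigma=sigma, n=n_draws,
                              region_id=f"R{i}")
        dc = degenerate_draws("cold", alpha=alpha, sigma=sigma, n=n_draws,
                              region_id=f"R{i}")
        x = np.full(n_days, 25.0)
        res = simulate_scenario(dw, dc, comfort(region_id=f"R{i}"), x,
                                seed=int(rng.integers(2**31)))
        # threshold placed inside the event-mean distribution's bulk
        q = rng.uniform(0.05, 0.95)
        thr_value = float(np.quantile(res.event_mean_draws, q))
        thr = EmergencyThreshold(f"R{i}", "warm", 0.75, thr_value)
        p = exceedance_probability(res, thr)
        # one independent realisation from the same true model
        obs = np.exp(rng.normal(alpha, sigma, n_days)).mean()
        probs.append(p)
        outcomes.append(obs > thr_value)
    probs = np.array(probs)
    outcomes = np.array(outcomes)
    for lo in np.arange(0.0, 1.0, 0.1):
        sel = (probs >= lo) & (probs < lo + 0.1)
        if sel.sum() < 15:
            continue
        freq = outcomes[sel].mean()
        expected = probs[sel].mean()
        se = np.sqrt(expected * (1 - expected) / sel.sum())
        assert abs(freq - expected) <= 3 * se + 0.02, (lo, freq, expected)
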
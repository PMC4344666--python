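import numpy as np
import pandas as pd
import pytest

import thermomort as tm
from thermomort.curves import BinnedCurve
from thermomort.preprocessing import RegionDailySeries


def make_series(tapp, rate, region_id="T", population=1e6):
    """Daily series with explicit apparent temperatures and rates.

    Dates are consecutive days; raw air/dew-point columns are irrelevant for
    curve/threshold computations, which consume tapp and rate directly.
    """
    tapp = np.asarray(tapp, dtype=float)
    rate = np.asarray(rate, dtype=float)
    n = len(tapp)
    deaths = rate * population / 1e6
    return RegionDailySeries(
        region_id=region_id,
        dates=pd.date_range("2000-01-01", periods=n, freq="D"),
        tair=np.zeros(n),
        tdewpt=np.zeros(n),
        deaths=deaths,
        population=np.full(n, population),
        tapp=tapp,
        rate=rate,
    )


def make_curve(log_rates, region_id="T", width=1.0, smoothed=None):
    """Binned curve with unit-width intervals anchored at 0."""
    log_rates = np.asarray(log_rates, dtype=float)
    n = len(log_rates)
    edges = width * np.arange(n + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    finite = np.isfinite(log_rates)
    return BinnedCurve(
        region_id=region_id,
        interval_edges=edges,
        n_days=finite.astype(int),
        mean_tapp=np.where(finite, centers, np.nan),
        mean_rate=np.where(finite, np.exp(log_rates), np.nan),
        log_mean_rate=log_rates,
        smoothed_log_rate=None if smoothed is None else np.asarray(smoothed, float),
    )


def flat_truth(intercept=np.log(25.0), population=2e6, sigma=0.0,
               temp_noise_sd=0.0, comfort=20.0):
    """Truth whose log-rate curve is constant (all cubic coefficients zero)."""
    return tm.RegionTruth(
        region_id="FLAT",
        population=population,
        comfort_temp=comfort,
        intercept_warm=intercept,
        intercept_cold=intercept,
        coef_warm=np.zeros(3),
        coef_cold=np.zeros(3),
        sigma_warm=sigma,
        sigma_cold=sigma,
        temp_mean=comfort - 4.0,
        temp_amplitude=10.0,
        temp_noise_sd=temp_noise_sd,
    )


@pytest.fixture(scope="session")
def panel54():
    """Default-condition synthetic panel: 54 regions x 6 years, lognormal."""
    return tm.generate_panel(54, n_years=6, seed=11, noise_mode="lognormal")


@pytest.fixture(scope="session")
def results54(panel54):
    return tm.MortalityEarlyWarning(panel54.series).fit()
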
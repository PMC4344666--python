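"""Probabilistic mortality simulation for temperature scenarios.

Given posterior draws for both tails of a region and a daily apparent
temperature series (a heat-wave or cold-spell episode), every day is routed
to the warm tail when its temperature is at or above the comfort
temperature and to the cold tail otherwise. For each posterior draw s and
day t a log mortality rate is simulated from

    y[s, t] ~ Normal(cubic_of_routed_tail(x_t; draw s), sigma[s]^2),

i.e. the posterior predictive including residual noise. Daily rates
exp(y) are averaged over the episode to an event-mean rate per draw, and
the forecast is the fraction of draws whose event mean strictly exceeds
the region's *emergency threshold* — the 75th percentile of the observed
daily mortality-rate distribution conditional on the relevant tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curves import ComfortTemperature
from .model import PosteriorDraws
from .preprocessing import RegionDailySeries

__all__ = [
    "EmergencyThreshold",
    "ScenarioResult",
    "compute_threshold",
    "simulate_scenario",
    "exceedance_probability",
]

DEFAULT_THRESHOLD_LEVEL = 0.75
MIN_TAIL_DAYS_FOR_THRESHOLD = 4


@dataclass
class EmergencyThreshold:
    """Tail-conditional quantile of a region's observed daily rates."""

    region_id: str
    tail: str  # "warm" | "cold"
    level: float  # quantile level in (0, 1)
    value: float  # deaths per million per day

    def __post_init__(self) -> None:
        if not 0 < self.level < 1:
            raise ValueError(f"quantile level must be in (0,1), got {self.level}")
        if self.value < 0:
            raise ValueError("threshold value must be >= 0")


@dataclass
class ScenarioResult:
    """Posterior predictive mortality for one region over one episode."""

    region_id: str
    dates: pd.DatetimeIndex
    x_it: np.ndarray  # daily apparent temperature, degC
    daily_draws: np.ndarray  # (n_samples, n_days) log rates
    event_mean_draws: np.ndarray  # (n_samples,) rates, deaths/million/day
    observed_event_mean: float | None = None
    exceedance_prob: float | None = None
    observed_exceeds: bool | None = None
    threshold: EmergencyThreshold | None = None

    @property
    def n_samples(self) -> int:
        return len(self.event_mean_draws)

    def summary_row(self) -> dict:
        """Per-region export row (GeoJSON property-join ready)."""
        q = np.quantile(self.event_mean_draws, [0.025, 0.5, 0.975])
        return {
            "region_id": self.region_id,
            "exceedance_prob": self.exceedance_prob,
            "observed_exceeds": self.observed_exceeds,
            "threshold": None if self.threshold is None else self.threshold.value,
            "event_mean_median": q[1],
            "event_mean_q025": q[0],
            "event_mean_q975": q[2],
        }


def compute_threshold(
    series: RegionDailySeries,
    comfort: ComfortTemperature,
    tail: str,
    level: float = DEFAULT_THRESHOLD_LEVEL,
) -> EmergencyThreshold:
    """Emergency threshold: tail-conditional empirical quantile of observed
    daily mortality rates.

    Days are assigned to the warm tail when ``tapp >= x_im`` and to the
    cold tail otherwise; the quantile uses linear interpolation between
    order statistics. Requires at least four days in the requested tail.
    """
    if tail not in ("warm", "cold"):
        raise ValueError(f"tail must be 'warm' or 'cold', got {tail!r}")
    if series.tapp is None or series.rate is None:
        raise ValueError("series lacks tapp/rate; run attach_rates first")
    if tail == "warm":
        mask = series.tapp >= comfort.x_im
    else:
        mask = series.tapp < comfort.x_im
    rates = series.rate[mask]
    if len(rates) == 0:
        raise ValueError(
            f"region {series.region_id!r}: no days in the {tail} tail"
        )
    if len(rates) < MIN_TAIL_DAYS_FOR_THRESHOLD:
        raise ValueError(
            f"region {series.region_id!r}: only {len(rates)} day(s) in the "
            f"{tail} tail, need >= {MIN_TAIL_DAYS_FOR_THRESHOLD}"
        )
    value = float(np.quantile(rates, level))  # linear interpolation
    return EmergencyThreshold(
        region_id=series.region_id, tail=tail, level=level, value=value
    )


def simulate_scenario(
    draws_warm: PosteriorDraws,
    draws_cold: PosteriorDraws,
    comfort: ComfortTemperature,
    x_series: pd.Series | np.ndarray,
    seed: int = 0,
    dates: pd.DatetimeIndex | None = None,
) -> ScenarioResult:
    """Posterior predictive simulation of an episode's mortality.

    ``x_series`` holds the episode's daily apparent temperatures (a pandas
    Series indexed by date, or a plain array plus ``dates``). Each day is
    routed to the warm tail when ``x >= x_im``, else cold; both tails'
    draws must share the sample count. Deterministic given ``seed``.
    """
    if isinstance(x_series, pd.Series):
        dates = pd.DatetimeIndex(x_series.index)
        x = x_series.to_numpy(dtype=float)
    else:
        x = np.asarray(x_series, dtype=float)
        if dates is None:
            dates = pd.DatetimeIndex(
                pd.date_range("2000-01-01", periods=len(x), freq="D")
            )
    if len(x) == 0:
        raise ValueError("scenario has no days")
    if draws_warm.n_samples != draws_cold.n_samples:
        raise ValueError(
            f"mismatched n_samples: warm {draws_warm.n_samples} vs "
            f"cold {draws_cold.n_samples}"
        )
    if draws_warm.region_id != draws_cold.region_id:
        raise ValueError("warm and cold draws come from different regions")

    warm_day = x >= comfort.x_im  # equality routed to the warm tail
    mu_warm = draws_warm.polyval(x)  # (S, T)
    mu_cold = draws_cold.polyval(x)
    mu = np.where(warm_day[None, :], mu_warm, mu_cold)
    sigma = np.where(
        warm_day[None, :], draws_warm.sigma[:, None], draws_cold.sigma[:, None]
    )
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(mu.shape)
    y = mu + sigma * z
    if not np.isfinite(y).all():
        raise ValueError(
            f"region {draws_warm.region_id!r}: non-finite simulated log rate "
            "(cubic evaluated far outside its fitted range?)"
        )
    event_mean = np.exp(y).mean(axis=1)
    return ScenarioResult(
        region_id=draws_warm.region_id,
        dates=dates,
        x_it=x,
        daily_draws=y,
        event_mean_draws=event_mean,
    )


def exceedance_probability(
    result: ScenarioResult,
    threshold: EmergencyThreshold,
    observed_event_mean: float | None = None,
) -> float:
    """Fraction of event-mean draws strictly above the emergency threshold.

    Mutates ``result`` in place (stores probability, threshold and — when an
    observation is supplied — the observed binary outcome) and returns the
    probability.
    """
    if result.n_samples == 0:
        raise ValueError("scenario result has no draws")
    if threshold.region_id != result.region_id:
        raise ValueError("threshold comes from a different region")
    prob = float(np.mean(result.event_mean_draws > threshold.value))
    result.exceedance_prob = prob
    result.threshold = threshold
    if observed_event_mean is None:
        observed_event_mean = result.observed_event_mean
    if observed_event_mean is not None:
        result.observed_event_mean = float(observed_event_mean)
        result.observed_exceeds = bool(observed_event_mean > threshold.value)
    return prob
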
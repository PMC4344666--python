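"""Synthetic multi-region mortality panels with known ground truth.

The generator emulates the statistical structure the analysis assumes: per
region a U/V/J-shaped log mortality-rate curve with its minimum at a
region-specific comfort temperature, a cold tail rising toward low
temperatures and a (often steeper) warm tail rising toward high ones, a
seasonal apparent-temperature cycle visiting both tails every year, and
daily noise — either log-normal on the rate (matching the model's
Normal-on-log-rate assumption exactly) or Poisson on the counts (stressing
robustness to count discreteness).

Ground-truth curves are parameterised as two cubics in ``u = x - comfort``
that share their value at the comfort temperature (curve continuity) and
are constrained monotone on the relevant side, so the comfort temperature
really is the temperature of minimum mortality. Coefficient triples
violating monotonicity on the plausible temperature range are resampled.

Default parameter ranges are calibrated to European daily mortality:
baseline around 20-35 deaths per million per day (roughly 1% annual
mortality), warm-tail log-slopes of 1-3% per degC and cold-tail slopes of
0.8-2.5% per degC near the comfort temperature, comfort temperatures
between 15 and 25 degC, and seasonal temperature amplitudes of 9-13 degC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocessing import (
    RegionDailySeries,
    attach_rates,
    invert_apparent_temperature,
    write_panel,
)

__all__ = [
    "RegionTruth",
    "TruthRanges",
    "SyntheticPanel",
    "generate_regions",
    "generate_daily_series",
    "generate_panel",
    "generate_scenario",
    "simulate_event_observations",
]

PEAK_DAY_OF_YEAR = 213  # Aug 1: warmest day of the seasonal cycle
DEFAULT_DEWPOINT = 6.0  # degC, held constant when back-solving air temp
WARM_CHECK_SPAN = 25.0  # degC above comfort over which monotonicity is enforced
COLD_CHECK_SPAN = 35.0  # degC below comfort
MONOTONE_GRID_STEP = 0.1  # degC
MAX_RESAMPLES = 200


@dataclass
class RegionTruth:
    """Ground-truth parameters of one synthetic region.

    ``coef_warm``/``coef_cold`` are cubic coefficient triples (per degC,
    degC^2, degC^3) acting on temperature centred at ``comfort_temp``;
    intercepts are log(deaths per million per day) at the comfort
    temperature and agree between tails (continuity at the minimum).
    """

    region_id: str
    population: float
    comfort_temp: float
    intercept_warm: float
    intercept_cold: float
    coef_warm: np.ndarray  # (3,)
    coef_cold: np.ndarray  # (3,)
    sigma_warm: float
    sigma_cold: float
    temp_mean: float
    temp_amplitude: float
    temp_noise_sd: float

    def __post_init__(self) -> None:
        self.coef_warm = np.asarray(self.coef_warm, dtype=float)
        self.coef_cold = np.asarray(self.coef_cold, dtype=float)
        if self.population <= 0:
            raise ValueError("population must be positive")
        if self.sigma_warm < 0 or self.sigma_cold < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.temp_amplitude < 0 or self.temp_noise_sd < 0:
            raise ValueError("temperature amplitude/noise must be >= 0")

    def log_rate(self, x) -> np.ndarray:
        """True log mortality rate at apparent temperature ``x`` (degC)."""
        x = np.asarray(x, dtype=float)
        u = x - self.comfort_temp
        warm = x >= self.comfort_temp
        b1w, b2w, b3w = self.coef_warm
        b1c, b2c, b3c = self.coef_cold
        yw = self.intercept_warm + b1w * u + b2w * u**2 + b3w * u**3
        yc = self.intercept_cold + b1c * u + b2c * u**2 + b3c * u**3
        return np.where(warm, yw, yc)

    def tail_sigma(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return np.where(x >= self.comfort_temp, self.sigma_warm, self.sigma_cold)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["coef_warm"] = self.coef_warm.tolist()
        d["coef_cold"] = self.coef_cold.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RegionTruth":
        return cls(**d)


@dataclass
class TruthRanges:
    """Uniform sampling intervals for every :class:`RegionTruth` field.

    ``temp_mean_offset`` is the gap between the comfort temperature and the
    annual-mean temperature (the annual mean sits below comfort, as in
    mid-latitude Europe where the comfort temperature is reached on warm
    days only), guaranteeing both tails are visited every year.
    """

    population: tuple = (5e5, 5e6)  # persons
    comfort_temp: tuple = (15.0, 25.0)  # degC
    log_base_rate: tuple = (np.log(20.0), np.log(35.0))  # log deaths/million/day
    warm_beta1: tuple = (0.010, 0.030)  # per degC
    warm_beta2: tuple = (0.001, 0.006)  # per degC^2
    warm_beta3: tuple = (-0.0003, 0.0008)  # per degC^3
    cold_beta1: tuple = (-0.025, -0.008)
    cold_beta2: tuple = (0.0, 0.0015)
    cold_beta3: tuple = (-0.0003, 0.0003)
    sigma_warm: tuple = (0.05, 0.15)  # log-rate daily SD
    sigma_cold: tuple = (0.05, 0.15)
    temp_mean_offset: tuple = (2.0, 6.0)  # comfort minus annual mean, degC
    temp_amplitude: tuple = (9.0, 13.0)  # degC
    temp_noise_sd: tuple = (1.5, 3.0)  # degC


def _warm_monotone(coefs: np.ndarray) -> bool:
    """Non-decreasing on [0, WARM_CHECK_SPAN]?"""
    u = np.arange(0.0, WARM_CHECK_SPAN + MONOTONE_GRID_STEP, MONOTONE_GRID_STEP)
    b1, b2, b3 = coefs
    y = b1 * u + b2 * u**2 + b3 * u**3
    return bool((np.diff(y) >= -1e-12).all())


def _cold_monotone(coefs: np.ndarray) -> bool:
    """Non-increasing in x on [-COLD_CHECK_SPAN, 0]?"""
    u = np.arange(-COLD_CHECK_SPAN, MONOTONE_GRID_STEP, MONOTONE_GRID_STEP)
    b1, b2, b3 = coefs
    y = b1 * u + b2 * u**2 + b3 * u**3
    return bool((np.diff(y) <= 1e-12).all())


def generate_regions(
    n_regions: int,
    seed: int,
    ranges: TruthRanges | None = None,
) -> list[RegionTruth]:
    """Sample ``n_regions`` ground-truth regions, deterministic given seed.

    Cubic coefficient triples are rejection-sampled until the warm curve is
    non-decreasing above the comfort temperature and the cold curve
    non-increasing below it, over the plausible temperature range; an
    unsatisfiable configuration fails explicitly naming the region index.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    r = ranges if ranges is not None else TruthRanges()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
    truths = []
    for i in range(n_regions):
        coef_warm = None
        for _ in range(MAX_RESAMPLES):
            cand = np.array(
                [
                    rng.uniform(*r.warm_beta1),
                    rng.uniform(*r.warm_beta2),
                    rng.uniform(*r.warm_beta3),
                ]
            )
            if _warm_monotone(cand):
                coef_warm = cand
                break
        if coef_warm is None:
            raise RuntimeError(
                f"region index {i}: no monotone warm-tail coefficient triple "
                f"found in {MAX_RESAMPLES} resamples; widen/repair the ranges"
            )
        coef_cold = None
        for _ in range(MAX_RESAMPLES):
            cand = np.array(
                [
                    rng.uniform(*r.cold_beta1),
                    rng.uniform(*r.cold_beta2),
                    rng.uniform(*r.cold_beta3),
                ]
            )
            if _cold_monotone(cand):
                coef_cold = cand
                break
        if coef_cold is None:
            raise RuntimeError(
                f"region index {i}: no monotone cold-tail coefficient triple "
                f"found in {MAX_RESAMPLES} resamples; widen/repair the ranges"
            )
        comfort = rng.uniform(*r.comfort_temp)
        intercept = rng.uniform(*r.log_base_rate)
        truths.append(
            RegionTruth(
                region_id=f"R{i:03d}",
                population=float(rng.uniform(*r.population)),
                comfort_temp=float(comfort),
                intercept_warm=float(intercept),  # continuity at the minimum
                intercept_cold=float(intercept),
                coef_warm=coef_warm,
                coef_cold=coef_cold,
                sigma_warm=float(rng.uniform(*r.sigma_warm)),
                sigma_cold=float(rng.uniform(*r.sigma_cold)),
                temp_mean=float(comfort - rng.uniform(*r.temp_mean_offset)),
                temp_amplitude=float(rng.uniform(*r.temp_amplitude)),
                temp_noise_sd=float(rng.uniform(*r.temp_noise_sd)),
            )
        )
    return truths


def seasonal_temperature(
    dates: pd.DatetimeIndex,
    temp_mean: float,
    temp_amplitude: float,
    peak_day: int = PEAK_DAY_OF_YEAR,
) -> np.ndarray:
    """Deterministic cosine seasonal cycle of daily apparent temperature."""
    doy = dates.dayofyear.to_numpy(dtype=float)
    return temp_mean + temp_amplitude * np.cos(
        2 * np.pi * (doy - peak_day) / 365.25
    )


def generate_daily_series(
    truth: RegionTruth,
    start_date: str = "1998-01-01",
    n_years: int = 6,
    seed: int = 0,
    noise_mode: str = "lognormal",
    dewpoint: float = DEFAULT_DEWPOINT,
) -> RegionDailySeries:
    """Simulate one region's daily panel over ``n_years`` calendar years.

    Daily apparent temperature is a cosine seasonal cycle (peaking on
    1 August) plus Gaussian noise; the true log rate comes from the tail
    curve at that temperature. ``lognormal`` mode draws the daily rate as
    exp(Normal(true log rate, sigma_tail)) and rounds to whole deaths;
    ``poisson_count`` mode draws deaths ~ Poisson(true rate x population).
    Air temperature is back-solved from the generated apparent temperature
    at a constant dew point, so preprocessing reproduces it exactly.
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    if noise_mode not in ("lognormal", "poisson_count"):
        raise ValueError(f"unknown noise_mode {noise_mode!r}")
    start = pd.Timestamp(start_date)
    end = start + pd.DateOffset(years=n_years)
    dates = pd.date_range(start, end - pd.Timedelta(days=1), freq="D")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1]))

    tapp = seasonal_temperature(dates, truth.temp_mean, truth.temp_amplitude)
    if truth.temp_noise_sd > 0:
        tapp = tapp + rng.normal(0.0, truth.temp_noise_sd, size=len(dates))
    log_rate = truth.log_rate(tapp)
    if not np.isfinite(log_rate).all():
        raise ValueError(
            f"region {truth.region_id!r}: non-finite true log rate "
            "(coefficients blow up outside the validated range)"
        )
    expected = np.exp(log_rate) * truth.population / 1e6  # deaths/day
    if noise_mode == "lognormal":
        sig = truth.tail_sigma(tapp)
        noisy_rate = np.exp(rng.normal(log_rate, sig))
        deaths = np.rint(noisy_rate * truth.population / 1e6)
    else:
        deaths = rng.poisson(expected).astype(float)

    tair = invert_apparent_temperature(tapp, dewpoint)
    series = RegionDailySeries(
        region_id=truth.region_id,
        dates=dates,
        tair=tair,
        tdewpt=np.full(len(dates), float(dewpoint)),
        deaths=deaths,
        population=np.full(len(dates), truth.population),
    )
    return attach_rates(series)


@dataclass
class SyntheticPanel:
    """A generated multi-region panel plus its ground truths."""

    series: dict[str, RegionDailySeries]
    truths: dict[str, RegionTruth]
    seed: int

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_panel(self.series, out / "panel.csv")
        payload = {rid: t.to_dict() for rid, t in sorted(self.truths.items())}
        with open(out / "truths.json", "w") as fh:
            json.dump(payload, fh, indent=2)

    @staticmethod
    def read_truths(path) -> dict[str, RegionTruth]:
        with open(path) as fh:
            payload = json.load(fh)
        return {rid: RegionTruth.from_dict(d) for rid, d in payload.items()}


def generate_panel(
    n_regions: int,
    n_years: int = 6,
    seed: int = 0,
    start_date: str = "1998-01-01",
    noise_mode: str = "lognormal",
    ranges: TruthRanges | None = None,
) -> SyntheticPanel:
    """Generate truths and daily series for a whole panel in one call."""
    truths = generate_regions(n_regions, seed=seed, ranges=ranges)
    series = {}
    for i, truth in enumerate(truths):
        region_seed = np.random.SeedSequence([int(seed), 1, i]).generate_state(1)[0]
        series[truth.region_id] = generate_daily_series(
            truth,
            start_date=start_date,
            n_years=n_years,
            seed=int(region_seed % (2**31)),
            noise_mode=noise_mode,
        )
    return SyntheticPanel(
        series=series,
        truths={t.region_id: t for t in truths},
        seed=seed,
    )


def generate_scenario(
    truths,
    kind: str,
    n_days: int = 15,
    seed: int = 0,
    severity: float = 8.0,
    noise_sd: float = 0.5,
    seasonal_offset: float = 5.0,
    start_date: str | None = None,
) -> pd.DataFrame:
    """Per-region daily apparent temperatures for a 15-day-style episode.

    ``heatwave``: temperatures at ``comfort + severity`` (plus small noise),
    all days in the warm tail. ``coldspell``: ``comfort - severity -
    seasonal_offset``, all days in the cold tail. Returns a tidy frame
    ``region_id, date, tapp_c``. Deterministic given seed.
    """
    if kind not in ("heatwave", "coldspell"):
        raise ValueError(f"kind must be 'heatwave' or 'coldspell', got {kind!r}")
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if start_date is None:
        start_date = "2003-08-01" if kind == "heatwave" else "2003-01-01"
    dates = pd.date_range(start_date, periods=n_days, freq="D")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2]))
    rows = []
    for truth in truths:
        if kind == "heatwave":
            base = truth.comfort_temp + severity
            noise = np.abs(rng.normal(0.0, noise_sd, size=n_days))  # stay warm
        else:
            base = truth.comfort_temp - severity - seasonal_offset
            noise = -np.abs(rng.normal(0.0, noise_sd, size=n_days))  # stay cold
        tapp = base + noise
        rows.append(
            pd.DataFrame(
                {"region_id": truth.region_id, "date": dates, "tapp_c": tapp}
            )
        )
    return pd.concat(rows, ignore_index=True)


def simulate_event_observations(
    truths,
    scenario: pd.DataFrame,
    seed: int = 0,
    noise_mode: str = "lognormal",
) -> pd.DataFrame:
    """Attach observed daily mortality rates (``obs_rate``) to a scenario.

    One stochastic realisation from the ground-truth model at the scenario
    temperatures — what would actually have been recorded during the
    episode. Counts are discretised through the region's population exactly
    as in :func:`generate_daily_series`.
    """
    by_id = {t.region_id: t for t in truths}
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 3]))
    out = scenario.copy()
    out["obs_rate"] = np.nan
    for region_id in sorted(by_id):
        mask = out["region_id"] == region_id
        if not mask.any():
            continue
        truth = by_id[region_id]
        tapp = out.loc[mask, "tapp_c"].to_numpy(dtype=float)
        log_rate = truth.log_rate(tapp)
        if noise_mode == "lognormal":
            sig = truth.tail_sigma(tapp)
            rate = np.exp(rng.normal(log_rate, sig))
            deaths = np.rint(rate * truth.population / 1e6)
        elif noise_mode == "poisson_count":
            deaths = rng.poisson(np.exp(log_rate) * truth.population / 1e6)
        else:
            raise ValueError(f"unknown noise_mode {noise_mode!r}")
        out.loc[mask, "obs_rate"] = deaths / truth.population * 1e6
    return out
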
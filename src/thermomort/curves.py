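"""Empirical temperature-mortality curve estimation.

The exposure-response curve of a region is estimated non-parametrically:
the observed apparent-temperature range is divided into equally spaced
intervals, daily temperature and mortality-rate observations are averaged
within each interval, and the log interval-mean rate is smoothed with a
centred moving-average filter. The minimum of the smoothed curve is the
*comfort temperature* (temperature of minimum mortality), which splits the
curve into a cold and a warm tail; each tail is later fitted with its own
cubic model.

Defaults follow the filter/interval correspondence of a 31-term filter
spanning roughly 3 degC, i.e. 0.1 degC intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .preprocessing import RegionDailySeries

__all__ = [
    "BinnedCurve",
    "ComfortTemperature",
    "TailDataset",
    "bin_series",
    "smooth_curve",
    "find_comfort_temperature",
    "split_tails",
]

DEFAULT_INTERVAL_WIDTH = 0.1  # degC
DEFAULT_FILTER_WINDOW = 31  # intervals; ~3 degC at default width
DEFAULT_MIN_DAYS_PER_INTERVAL = 1
DEFAULT_MIN_TAIL_POINTS = 8  # 2 x number of cubic parameters


@dataclass
class BinnedCurve:
    """Per-interval means of temperature and mortality rate for one region.

    Intervals are half-open ``[lo, hi)``, equally spaced, left-anchored at
    the observed minimum apparent temperature. ``log_mean_rate`` is
    ``log(mean(rate))`` within the interval — average first, then log — and
    is NaN where the interval is unpopulated (fewer than
    ``min_days_per_interval`` days, or zero mean rate).
    """

    region_id: str
    interval_edges: np.ndarray  # length n_intervals + 1
    n_days: np.ndarray  # int, per interval
    mean_tapp: np.ndarray  # NaN where missing
    mean_rate: np.ndarray  # NaN where missing
    log_mean_rate: np.ndarray  # NaN where missing
    smoothed_log_rate: np.ndarray | None = None
    min_days_per_interval: int = DEFAULT_MIN_DAYS_PER_INTERVAL

    @property
    def interval_centers(self) -> np.ndarray:
        return 0.5 * (self.interval_edges[:-1] + self.interval_edges[1:])

    @property
    def populated(self) -> np.ndarray:
        """Mask of intervals with a defined log mean rate."""
        return np.isfinite(self.log_mean_rate)

    @property
    def n_intervals(self) -> int:
        return len(self.n_days)


@dataclass
class ComfortTemperature:
    """Temperature of minimum mortality on the smoothed curve."""

    region_id: str
    x_im: float  # interval centre, degC
    interval_index: int
    boundary: bool = False  # argmin at the first/last populated interval


@dataclass
class TailDataset:
    """Interval points retained for one tail's cubic fit.

    Warm tail holds intervals with ``mean_tapp >= x_im`` (equality is warm);
    cold tail holds ``mean_tapp < x_im``.
    """

    region_id: str
    tail: str  # "warm" | "cold"
    x: np.ndarray  # interval mean tapp, degC
    y: np.ndarray  # log interval-mean rate
    weights: np.ndarray | None = None  # n_days per interval


def bin_series(
    series: RegionDailySeries,
    interval_width: float = DEFAULT_INTERVAL_WIDTH,
    min_days_per_interval: int = DEFAULT_MIN_DAYS_PER_INTERVAL,
) -> BinnedCurve:
    """Group days into equally spaced apparent-temperature intervals.

    Within each interval the member days' apparent temperatures and
    mortality rates are averaged; the log of the mean rate becomes the
    response fitted downstream. Intervals with fewer than
    ``min_days_per_interval`` days are flagged missing (NaN); a populated
    interval whose mean rate is exactly zero is also flagged missing, with a
    warning, since its log is undefined.
    """
    if interval_width <= 0:
        raise ValueError("interval_width must be positive")
    if series.tapp is None or series.rate is None:
        raise ValueError(
            f"region {series.region_id!r}: series lacks tapp/rate; "
            "run preprocessing.attach_rates first"
        )
    tapp = series.tapp
    rate = series.rate
    lo = float(tapp.min())
    n_bins = int(np.floor((tapp.max() - lo) / interval_width)) + 1
    edges = lo + interval_width * np.arange(n_bins + 1)
    idx = np.floor((tapp - lo) / interval_width).astype(int)
    idx = np.clip(idx, 0, n_bins - 1)  # guards float roundoff at the max

    n_days = np.bincount(idx, minlength=n_bins)
    sum_tapp = np.bincount(idx, weights=tapp, minlength=n_bins)
    sum_rate = np.bincount(idx, weights=rate, minlength=n_bins)

    with np.errstate(invalid="ignore", divide="ignore"):
        mean_tapp = np.where(n_days > 0, sum_tapp / np.maximum(n_days, 1), np.nan)
        mean_rate = np.where(n_days > 0, sum_rate / np.maximum(n_days, 1), np.nan)

    ok = n_days >= max(min_days_per_interval, 1)
    zero_rate = ok & (mean_rate == 0)
    if zero_rate.any():
        warnings.warn(
            f"region {series.region_id!r}: {int(zero_rate.sum())} populated "
            "interval(s) with zero mean mortality rate flagged missing "
            "(log undefined)",
            stacklevel=2,
        )
        ok &= ~zero_rate
    if not ok.any():
        raise ValueError(
            f"region {series.region_id!r}: no interval satisfies "
            f"min_days_per_interval={min_days_per_interval}"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        log_mean_rate = np.where(ok, np.log(np.where(ok, mean_rate, 1.0)), np.nan)
    mean_tapp = np.where(ok | (n_days > 0), mean_tapp, np.nan)
    mean_rate = np.where(ok | (n_days > 0), mean_rate, np.nan)

    return BinnedCurve(
        region_id=series.region_id,
        interval_edges=edges,
        n_days=n_days,
        mean_tapp=mean_tapp,
        mean_rate=mean_rate,
        log_mean_rate=log_mean_rate,
        min_days_per_interval=min_days_per_interval,
    )


def smooth_curve(
    curve: BinnedCurve,
    window: int = DEFAULT_FILTER_WINDOW,
    scale: str = "log",
) -> BinnedCurve:
    """Apply a centred ``window``-term moving-average filter.

    Windows truncate (shrink) at the ends of the curve so the smoothed
    series keeps the full temperature range; missing intervals inside a
    window are skipped in the average. ``scale="log"`` (default) smooths the
    log mean rate directly; ``scale="rate"`` averages mean rates and takes
    the log afterwards. The smoothed value is left NaN where the raw
    interval itself is missing, so the comfort-temperature search never
    lands on an unobserved interval.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    if scale not in ("log", "rate"):
        raise ValueError(f"scale must be 'log' or 'rate', got {scale!r}")
    half = window // 2
    if scale == "log":
        values = curve.log_mean_rate
    else:
        values = np.where(curve.populated, curve.mean_rate, np.nan)
    n = len(values)
    smoothed = np.full(n, np.nan)
    finite = np.isfinite(values)
    csum = np.cumsum(np.where(finite, values, 0.0))
    ccnt = np.cumsum(finite.astype(int))
    for k in np.nonzero(finite)[0]:
        a = max(0, k - half)
        b = min(n, k + half + 1)  # exclusive
        cnt = ccnt[b - 1] - (ccnt[a - 1] if a > 0 else 0)
        tot = csum[b - 1] - (csum[a - 1] if a > 0 else 0)
        if cnt > 0:
            smoothed[k] = tot / cnt
    if scale == "rate":
        with np.errstate(invalid="ignore", divide="ignore"):
            smoothed = np.where(smoothed > 0, np.log(smoothed), np.nan)
    return replace(curve, smoothed_log_rate=smoothed)


def find_comfort_temperature(curve: BinnedCurve) -> ComfortTemperature:
    """Locate the global minimum of the smoothed curve.

    Ties break toward the lower temperature. If the minimum sits at the
    first or last populated interval the curve is monotone over the
    observed range (no interior minimum); a warning is emitted and the
    result flagged ``boundary=True``.
    """
    if curve.smoothed_log_rate is None:
        raise ValueError("curve has no smoothed_log_rate; run smooth_curve first")
    sm = curve.smoothed_log_rate
    finite = np.nonzero(np.isfinite(sm))[0]
    if len(finite) == 0:
        raise ValueError(
            f"region {curve.region_id!r}: no non-missing smoothed values"
        )
    k = int(finite[np.argmin(sm[finite])])  # argmin takes the first -> lower T
    boundary = k == finite[0] or k == finite[-1]
    if boundary:
        warnings.warn(
            f"region {curve.region_id!r}: comfort temperature at the boundary "
            "of the observed range (monotone curve)",
            stacklevel=2,
        )
    return ComfortTemperature(
        region_id=curve.region_id,
        x_im=float(curve.interval_centers[k]),
        interval_index=k,
        boundary=boundary,
    )


def split_tails(
    curve: BinnedCurve,
    comfort: ComfortTemperature,
    min_tail_points: int = DEFAULT_MIN_TAIL_POINTS,
) -> tuple[TailDataset, TailDataset]:
    """Partition populated intervals into (cold, warm) tail datasets.

    An interval belongs to the warm tail when its mean apparent temperature
    is >= the comfort temperature (equality is warm), to the cold tail
    otherwise. Raises if either tail retains fewer than ``min_tail_points``
    intervals, naming the deficient tail — a cubic is unidentifiable there.
    """
    if comfort.region_id != curve.region_id:
        raise ValueError("comfort temperature comes from a different region")
    pop = curve.populated
    x = curve.mean_tapp
    warm_mask = pop & (x >= comfort.x_im)
    cold_mask = pop & (x < comfort.x_im)
    for tail, mask in (("cold", cold_mask), ("warm", warm_mask)):
        if int(mask.sum()) < min_tail_points:
            raise ValueError(
                f"region {curve.region_id!r}: {tail} tail has only "
                f"{int(mask.sum())} interval(s), need >= {min_tail_points}"
            )
    cold = TailDataset(
        region_id=curve.region_id,
        tail="cold",
        x=x[cold_mask].copy(),
        y=curve.log_mean_rate[cold_mask].copy(),
        weights=curve.n_days[cold_mask].copy(),
    )
    warm = TailDataset(
        region_id=curve.region_id,
        tail="warm",
        x=x[warm_mask].copy(),
        y=curve.log_mean_rate[warm_mask].copy(),
        weights=curve.n_days[warm_mask].copy(),
    )
    return cold, warm
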
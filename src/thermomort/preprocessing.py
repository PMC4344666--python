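"""Raw daily records -> analysis-ready series.

Two derived quantities drive everything downstream:

* **apparent temperature** ``Tapp``, a humidity-adjusted exposure index
  combining air and dew-point temperature, and
* the daily **mortality rate** per million population.

The canonical container is :class:`RegionDailySeries`: one region's complete,
gap-free daily record of climate and mortality.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "APPARENT_TEMP_INTERCEPT",
    "APPARENT_TEMP_TAIR_COEF",
    "APPARENT_TEMP_TDEW_COEF",
    "RegionDailySeries",
    "apparent_temperature",
    "invert_apparent_temperature",
    "attach_rates",
    "read_panel",
    "write_panel",
]

# Tapp = -2.653 + 0.994 * Tair + 0.0153 * Tdewpt^2, all in degC.
APPARENT_TEMP_INTERCEPT = -2.653
APPARENT_TEMP_TAIR_COEF = 0.994
APPARENT_TEMP_TDEW_COEF = 0.0153

#: Column order of the on-disk daily panel format.
PANEL_COLUMNS = ["region_id", "date", "tair_c", "tdewpt_c", "deaths", "population"]


def apparent_temperature(tair, tdewpt):
    """Apparent (humidity-adjusted) temperature in degC.

    Computes ``-2.653 + 0.994*Tair + 0.0153*Tdewpt**2`` elementwise. The
    dew-point term is squared as printed, so sub-zero dew points contribute
    positively like their positive mirror.

    Parameters
    ----------
    tair, tdewpt : float or array-like
        Daily mean air and dew-point temperature in degC. Must be finite.

    Raises
    ------
    ValueError
        If any input element is non-finite; the offending position is named.
    """
    tair = np.asarray(tair, dtype=float)
    tdewpt = np.asarray(tdewpt, dtype=float)
    for name, arr in (("tair", tair), ("tdewpt", tdewpt)):
        bad = ~np.isfinite(arr)
        if bad.any():
            idx = int(np.argmax(bad))
            raise ValueError(
                f"non-finite {name} at position {idx}: {arr.reshape(-1)[idx]!r}"
            )
    out = (
        APPARENT_TEMP_INTERCEPT
        + APPARENT_TEMP_TAIR_COEF * tair
        + APPARENT_TEMP_TDEW_COEF * tdewpt**2
    )
    if out.ndim == 0:
        return float(out)
    return out


def invert_apparent_temperature(tapp, tdewpt):
    """Air temperature that reproduces ``tapp`` at the given dew point.

    Inverse of :func:`apparent_temperature` in its (linear) air-temperature
    argument; used by the synthetic generator to back-fill raw columns.
    """
    tapp = np.asarray(tapp, dtype=float)
    tdewpt = np.asarray(tdewpt, dtype=float)
    tair = (
        tapp - APPARENT_TEMP_INTERCEPT - APPARENT_TEMP_TDEW_COEF * tdewpt**2
    ) / APPARENT_TEMP_TAIR_COEF
    if tair.ndim == 0:
        return float(tair)
    return tair


@dataclass
class RegionDailySeries:
    """One region's daily climate and mortality observations.

    Dates must be strictly increasing at daily resolution with no gaps;
    missing days are rejected rather than imputed because the interval
    binning downstream assumes complete coverage.
    """

    region_id: str
    dates: pd.DatetimeIndex
    tair: np.ndarray
    tdewpt: np.ndarray
    deaths: np.ndarray
    population: np.ndarray
    tapp: np.ndarray | None = None
    rate: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        n = len(self.dates)
        for name in ("tair", "tdewpt", "deaths", "population"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(
                    f"{name} has shape {arr.shape}, expected ({n},) "
                    f"for region {self.region_id!r}"
                )
            setattr(self, name, arr)
        if n == 0:
            raise ValueError(f"empty series for region {self.region_id!r}")
        deltas = np.diff(self.dates.values).astype("timedelta64[D]").astype(int)
        if n > 1 and not (deltas == 1).all():
            bad = int(np.argmax(deltas != 1))
            raise ValueError(
                f"region {self.region_id!r}: dates not strictly daily at "
                f"{self.dates[bad].date()} -> {self.dates[bad + 1].date()}"
            )
        if (self.deaths < 0).any():
            bad = int(np.argmax(self.deaths < 0))
            raise ValueError(
                f"region {self.region_id!r}: negative deaths on "
                f"{self.dates[bad].date()}"
            )

    def __len__(self) -> int:
        return len(self.dates)

    def with_tapp(self) -> "RegionDailySeries":
        """Return a copy with the apparent-temperature column populated."""
        return replace(self, tapp=apparent_temperature(self.tair, self.tdewpt))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "region_id": self.region_id,
                "date": self.dates,
                "tair_c": self.tair,
                "tdewpt_c": self.tdewpt,
                "deaths": self.deaths.astype(int),
                "population": self.population,
            }
        )
        if self.tapp is not None:
            df["tapp_c"] = self.tapp
        if self.rate is not None:
            df["rate"] = self.rate
        return df


def attach_rates(series: RegionDailySeries) -> RegionDailySeries:
    """Populate ``rate`` (deaths per million population per day) and ``tapp``.

    Idempotent. Raises ``ValueError`` if any day's population is <= 0.
    """
    if (series.population <= 0).any():
        bad = int(np.argmax(series.population <= 0))
        raise ValueError(
            f"region {series.region_id!r}: population <= 0 on "
            f"{series.dates[bad].date()}"
        )
    out = series if series.tapp is not None else series.with_tapp()
    rate = out.deaths / out.population * 1e6
    return replace(out, rate=rate)


def read_panel(path) -> dict[str, RegionDailySeries]:
    """Read a multi-region daily panel from delimited text.

    Expects the header ``region_id,date,tair_c,tdewpt_c,deaths,population``
    with ISO-8601 dates. Returns analysis-ready series (tapp and rate
    attached), keyed by region id in sorted order.
    """
    df = pd.read_csv(path, parse_dates=["date"])
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"panel {path}: missing columns {missing}")
    out: dict[str, RegionDailySeries] = {}
    for region_id in sorted(df["region_id"].astype(str).unique()):
        sub = df[df["region_id"].astype(str) == region_id].sort_values("date")
        series = RegionDailySeries(
            region_id=region_id,
            dates=pd.DatetimeIndex(sub["date"]),
            tair=sub["tair_c"].to_numpy(),
            tdewpt=sub["tdewpt_c"].to_numpy(),
            deaths=sub["deaths"].to_numpy(),
            population=sub["population"].to_numpy(),
        )
        out[region_id] = attach_rates(series)
    return out


def write_panel(series_by_region: dict[str, RegionDailySeries], path) -> None:
    """Write a panel in the canonical delimited format (ISO-8601 dates)."""
    frames = []
    for region_id in sorted(series_by_region):
        df = series_by_region[region_id].to_frame()[PANEL_COLUMNS].copy()
        df["date"] = df["date"].dt.strftime("%Y-%m-%d")
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
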
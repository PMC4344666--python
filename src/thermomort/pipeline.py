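"""End-to-end analysis: panel in, verified probabilistic warnings out.

:class:`MortalityEarlyWarning` is the panel-level model object: built from
a multi-region daily panel (constructor, ``from_dataframe`` or
``from_csv``), its :meth:`~MortalityEarlyWarning.fit` estimates every
region's empirical curve, comfort temperature, two cubic tail posteriors
and emergency thresholds, returning a
:class:`MortalityEarlyWarningResults` that predicts scenarios and writes
all artifacts. Randomness is governed by a single seed split
deterministically into per-stage, per-region substreams, so re-running —
or parallelising over regions — cannot change results.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import curves as _curves
from .curves import (
    BinnedCurve,
    ComfortTemperature,
    TailDataset,
    bin_series,
    find_comfort_temperature,
    smooth_curve,
    split_tails,
)
from .model import PosteriorDraws, PriorSpec, fit_tail
from .preprocessing import RegionDailySeries, read_panel, attach_rates
from .scenario import (
    EmergencyThreshold,
    ScenarioResult,
    compute_threshold,
    exceedance_probability,
    simulate_scenario,
)
from .verification import verification_table

__all__ = [
    "PipelineConfig",
    "RegionFit",
    "MortalityEarlyWarning",
    "MortalityEarlyWarningResults",
    "run_pipeline",
]

logger = logging.getLogger("thermomort")

_STAGE_FIT = 10
_STAGE_PREDICT = 20


def _substream_seed(seed: int, stage: int, index: int) -> int:
    """Deterministic per-stage, per-region child seed (< 2**31)."""
    state = np.random.SeedSequence([int(seed), stage, index]).generate_state(1)[0]
    return int(state % (2**31))


@dataclass
class PipelineConfig:
    """All tunables of the pipeline; round-trips through JSON unchanged."""

    interval_width: float = 0.1  # degC
    filter_window: int = 31  # intervals, odd
    min_days_per_interval: int = 1
    min_tail_points: int = 8
    n_samples: int = 1000
    quantile_level: float = 0.75
    decision_thresholds: tuple = (0.3, 0.7)
    prior: PriorSpec = field(default_factory=PriorSpec)
    seed: int = 0
    smoothing_scale: str = "log"  # "log" | "rate"
    fit_input: str = "raw"  # "raw" | "smoothed"

    def __post_init__(self) -> None:
        if self.interval_width <= 0:
            raise ValueError("interval_width must be positive")
        if self.filter_window < 1 or self.filter_window % 2 == 0:
            raise ValueError("filter_window must be odd and >= 1")
        if self.min_days_per_interval < 1:
            raise ValueError("min_days_per_interval must be >= 1")
        if self.min_tail_points < 4:
            raise ValueError("min_tail_points must be >= 4 (cubic has 4 params)")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not 0 < self.quantile_level < 1:
            raise ValueError("quantile_level must be in (0,1)")
        self.decision_thresholds = tuple(float(t) for t in self.decision_thresholds)
        for t in self.decision_thresholds:
            if not 0 <= t <= 1:
                raise ValueError("decision thresholds must be in [0,1]")
        if self.smoothing_scale not in ("log", "rate"):
            raise ValueError("smoothing_scale must be 'log' or 'rate'")
        if self.fit_input not in ("raw", "smoothed"):
            raise ValueError("fit_input must be 'raw' or 'smoothed'")
        if isinstance(self.prior, dict):
            self.prior = PriorSpec.from_dict(self.prior)

    def to_dict(self) -> dict:
        return {
            "interval_width": self.interval_width,
            "filter_window": self.filter_window,
            "min_days_per_interval": self.min_days_per_interval,
            "min_tail_points": self.min_tail_points,
            "n_samples": self.n_samples,
            "quantile_level": self.quantile_level,
            "decision_thresholds": list(self.decision_thresholds),
            "prior": self.prior.to_dict(),
            "seed": self.seed,
            "smoothing_scale": self.smoothing_scale,
            "fit_input": self.fit_input,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "prior" in d and isinstance(d["prior"], dict):
            d["prior"] = PriorSpec.from_dict(d["prior"])
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({**self.to_dict(), "config_hash": self.hash()}, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = json.load(fh)
        d.pop("config_hash", None)
        return cls.from_dict(d)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RegionFit:
    """Everything estimated for one region."""

    region_id: str
    curve: BinnedCurve
    comfort: ComfortTemperature
    tail_cold: TailDataset
    tail_warm: TailDataset
    draws_cold: PosteriorDraws
    draws_warm: PosteriorDraws
    threshold_cold: EmergencyThreshold
    threshold_warm: EmergencyThreshold


class MortalityEarlyWarning:
    """Panel-level model: daily series per region + configuration."""

    def __init__(
        self,
        series_by_region: dict[str, RegionDailySeries],
        config: PipelineConfig | None = None,
    ) -> None:
        if not series_by_region:
            raise ValueError("panel contains no regions")
        self.series_by_region = dict(sorted(series_by_region.items()))
        self.config = config if config is not None else PipelineConfig()

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, config: PipelineConfig | None = None
    ) -> "MortalityEarlyWarning":
        """Build from a tidy panel frame with the canonical columns
        ``region_id, date, tair_c, tdewpt_c, deaths, population``."""
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
        return cls(out, config=config)

    @classmethod
    def from_csv(
        cls, path, config: PipelineConfig | None = None
    ) -> "MortalityEarlyWarning":
        return cls(read_panel(path), config=config)

    def fit(self) -> "MortalityEarlyWarningResults":
        """Estimate curves, comfort temperatures, tail posteriors and
        emergency thresholds for every region."""
        cfg = self.config
        fits: dict[str, RegionFit] = {}
        skipped: dict[str, str] = {}
        for index, (region_id, series) in enumerate(self.series_by_region.items()):
            try:
                curve = bin_series(
                    series,
                    interval_width=cfg.interval_width,
                    min_days_per_interval=cfg.min_days_per_interval,
                )
                curve = smooth_curve(
                    curve, window=cfg.filter_window, scale=cfg.smoothing_scale
                )
                comfort = find_comfort_temperature(curve)
                fit_curve = curve
                if cfg.fit_input == "smoothed":
                    fit_curve = replace(
                        curve, log_mean_rate=curve.smoothed_log_rate
                    )
                cold, warm = split_tails(
                    fit_curve, comfort, min_tail_points=cfg.min_tail_points
                )
                seed = _substream_seed(cfg.seed, _STAGE_FIT, index)
                draws_cold = fit_tail(
                    cold,
                    centering=comfort.x_im,
                    prior=cfg.prior,
                    n_samples=cfg.n_samples,
                    seed=seed,
                )
                draws_warm = fit_tail(
                    warm,
                    centering=comfort.x_im,
                    prior=cfg.prior,
                    n_samples=cfg.n_samples,
                    seed=seed + 1,
                )
                thr_cold = compute_threshold(
                    series, comfort, "cold", level=cfg.quantile_level
                )
                thr_warm = compute_threshold(
                    series, comfort, "warm", level=cfg.quantile_level
                )
            except (ValueError, RuntimeError) as exc:
                logger.warning("region %s skipped: %s", region_id, exc)
                skipped[region_id] = str(exc)
                continue
            if comfort.boundary:
                logger.warning(
                    "region %s: boundary comfort temperature %.2f degC",
                    region_id,
                    comfort.x_im,
                )
            logger.info(
                "region %s: comfort %.2f degC, %d cold / %d warm intervals",
                region_id,
                comfort.x_im,
                len(cold.x),
                len(warm.x),
            )
            fits[region_id] = RegionFit(
                region_id=region_id,
                curve=curve,
                comfort=comfort,
                tail_cold=cold,
                tail_warm=warm,
                draws_cold=draws_cold,
                draws_warm=draws_warm,
                threshold_cold=thr_cold,
                threshold_warm=thr_warm,
            )
        if not fits:
            raise RuntimeError("no region could be fitted; see log for reasons")
        return MortalityEarlyWarningResults(self, fits, skipped)


class MortalityEarlyWarningResults:
    """Fitted panel: per-region curves, posteriors, thresholds; predicts
    scenarios and serialises artifacts."""

    def __init__(
        self,
        model: MortalityEarlyWarning,
        region_fits: dict[str, RegionFit],
        skipped: dict[str, str] | None = None,
    ) -> None:
        self.model = model
        self.config = model.config
        self.region_fits = region_fits
        self.skipped = skipped or {}

    @property
    def region_ids(self) -> list[str]:
        return list(self.region_fits)

    def comfort_frame(self) -> pd.DataFrame:
        rows = [
            {
                "region_id": rid,
                "comfort_temp_c": f.comfort.x_im,
                "interval_index": f.comfort.interval_index,
                "boundary": f.comfort.boundary,
                "threshold_warm": f.threshold_warm.value,
                "threshold_cold": f.threshold_cold.value,
            }
            for rid, f in self.region_fits.items()
        ]
        return pd.DataFrame(rows)

    def curves_frame(self) -> pd.DataFrame:
        frames = []
        for rid, f in self.region_fits.items():
            c = f.curve
            frames.append(
                pd.DataFrame(
                    {
                        "region_id": rid,
                        "interval_center_c": c.interval_centers,
                        "n_days": c.n_days,
                        "mean_tapp_c": c.mean_tapp,
                        "mean_rate": c.mean_rate,
                        "log_mean_rate": c.log_mean_rate,
                        "smoothed_log_rate": c.smoothed_log_rate,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def draws_frame(self) -> pd.DataFrame:
        frames = []
        for rid, f in self.region_fits.items():
            for draws in (f.draws_cold, f.draws_warm):
                df = draws.to_frame()
                df.insert(0, "region_id", rid)
                df.insert(1, "tail", draws.tail)
                df.insert(2, "centering", draws.centering)
                frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def predict_scenario(
        self,
        scenario: pd.DataFrame,
        tail: str = "warm",
        seed: int | None = None,
    ) -> tuple[pd.DataFrame, dict[str, ScenarioResult]]:
        """Probabilistic forecasts for a scenario episode.

        ``scenario`` is tidy: ``region_id, date, tapp_c`` and optionally
        ``obs_rate`` (observed daily mortality rate, used to score the
        forecast). ``tail`` selects which emergency threshold applies —
        warm for heat waves, cold for cold spells. Returns the per-region
        forecast frame and the full simulation objects.
        """
        if tail not in ("warm", "cold"):
            raise ValueError("tail must be 'warm' or 'cold'")
        base_seed = self.config.seed if seed is None else seed
        rows = []
        results: dict[str, ScenarioResult] = {}
        scen_ids = sorted(scenario["region_id"].astype(str).unique())
        for index, region_id in enumerate(scen_ids):
            f = self.region_fits.get(region_id)
            if f is None:
                logger.warning("scenario region %s has no fit; skipped", region_id)
                continue
            sub = scenario[scenario["region_id"].astype(str) == region_id]
            sub = sub.sort_values("date")
            x = pd.Series(
                sub["tapp_c"].to_numpy(dtype=float),
                index=pd.DatetimeIndex(sub["date"]),
            )
            result = simulate_scenario(
                f.draws_warm,
                f.draws_cold,
                f.comfort,
                x,
                seed=_substream_seed(base_seed, _STAGE_PREDICT, index),
            )
            threshold = f.threshold_warm if tail == "warm" else f.threshold_cold
            observed = None
            if "obs_rate" in sub.columns and sub["obs_rate"].notna().all():
                observed = float(sub["obs_rate"].mean())
            exceedance_probability(result, threshold, observed_event_mean=observed)
            results[region_id] = result
            rows.append(result.summary_row())
        if not rows:
            raise ValueError("scenario covers no fitted region")
        return pd.DataFrame(rows), results

    def summary(self) -> str:
        cf = self.comfort_frame()
        lines = [
            "Temperature-mortality early-warning model",
            f"regions fitted: {len(self.region_fits)}"
            + (f" (skipped: {len(self.skipped)})" if self.skipped else ""),
            f"posterior draws per tail: {self.config.n_samples}",
            f"comfort temperature: median {cf['comfort_temp_c'].median():.1f} degC, "
            f"range {cf['comfort_temp_c'].min():.1f}-"
            f"{cf['comfort_temp_c'].max():.1f} degC",
            f"emergency threshold: {self.config.quantile_level:.0%} quantile of "
            "tail-conditional daily rates",
            f"config hash: {self.config.hash()}  seed: {self.config.seed}",
        ]
        return "\n".join(lines)

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.config.to_json(out / "config.json")
        self.curves_frame().to_csv(out / "curves.csv", index=False)
        self.comfort_frame().to_csv(out / "comfort.csv", index=False)
        self.draws_frame().to_csv(out / "draws.csv", index=False)
        if self.skipped:
            with open(out / "skipped.json", "w") as fh:
                json.dump(self.skipped, fh, indent=2)


def run_pipeline(
    config: PipelineConfig,
    panel_path,
    scenario_path,
    out_dir,
    scenario_tail: str = "warm",
    scenario_name: str = "scenario",
) -> MortalityEarlyWarningResults:
    """Fit the panel, predict the scenario, verify, and write all artifacts.

    Artifacts (config + hash, curves, comfort temperatures, posterior
    draws, forecasts, verification metrics) land in ``out_dir``; the
    verification step runs only when the scenario file carries observed
    rates. Byte-identical outputs under identical config and seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = MortalityEarlyWarning.from_csv(panel_path, config=config)
    results = model.fit()
    results.save(out)

    scenario = pd.read_csv(scenario_path, parse_dates=["date"])
    required = {"region_id", "date", "tapp_c"}
    missing = required - set(scenario.columns)
    if missing:
        raise ValueError(f"scenario {scenario_path}: missing columns {sorted(missing)}")
    forecasts, _ = results.predict_scenario(scenario, tail=scenario_tail)
    forecasts.insert(1, "config_hash", config.hash())
    forecasts.insert(2, "seed", config.seed)
    forecasts.to_csv(out / "forecasts.csv", index=False)

    if forecasts["observed_exceeds"].notna().all():
        table = verification_table(
            forecasts,
            decision_thresholds=config.decision_thresholds,
            scenario=scenario_name,
            threshold_level=config.quantile_level,
        )
        table.to_csv(out / "verification.csv", index=False)
        with open(out / "metrics.json", "w") as fh:
            json.dump(
                {
                    "scenario": scenario_name,
                    "config_hash": config.hash(),
                    "seed": config.seed,
                    "rows": table.drop(columns=["scenario"]).to_dict("records"),
                },
                fh,
                indent=2,
            )
    else:
        logger.info("no observed outcomes in scenario; verification skipped")
    return results
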
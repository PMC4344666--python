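"""Forecast verification in a binary framework.

Each region contributes one probabilistic forecast (probability that its
event-mean mortality rate exceeds the emergency threshold) and one observed
binary outcome. A *decision threshold* converts probabilities to warnings
(predicted positive iff probability >= threshold — a stated 70% trigger
fires at exactly 70%); the resulting 2x2 contingency table yields the hit
rate (sensitivity), false-alarm rate (1 - specificity) and proportion
correct. Sweeping the decision threshold over the unique forecast
probabilities traces the ROC curve, whose trapezoidal area (the ROC score)
equals the tie-corrected Mann-Whitney probability: 0.5 is zero skill,
1.0 perfect skill.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "ContingencyTable",
    "VerificationMetrics",
    "ROCCurve",
    "make_contingency",
    "metrics",
    "roc",
    "verification_table",
]

DEFAULT_DECISION_THRESHOLDS = (0.3, 0.7)  # cautious / strict


@dataclass
class ContingencyTable:
    """Counts of regions by (predicted, observed) warning status."""

    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int

    def __post_init__(self) -> None:
        for name in ("hits", "misses", "false_alarms", "correct_rejections"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer")
            setattr(self, name, int(v))

    @property
    def total(self) -> int:
        return self.hits + self.misses + self.false_alarms + self.correct_rejections


@dataclass
class VerificationMetrics:
    """Binary-forecast scores; a rate with an empty denominator is ``None``
    (undefined), never silently zero."""

    hit_rate: float | None
    false_alarm_rate: float | None
    proportion_correct: float
    decision_threshold: float | None = None


@dataclass
class ROCCurve:
    """(false-alarm rate, hit rate) points and the area under them."""

    points: np.ndarray  # (k, 2) sorted by FAR, including (0,0) and (1,1)
    auc: float
    thresholds: np.ndarray  # decision thresholds generating the points


def _validate(probs, observed) -> tuple[np.ndarray, np.ndarray]:
    probs = np.asarray(probs, dtype=float)
    observed = np.asarray(observed, dtype=bool)
    if probs.ndim != 1 or probs.shape != observed.shape:
        raise ValueError("probs and observed must be equal-length 1-D arrays")
    if len(probs) == 0:
        raise ValueError("need at least one region")
    if ((probs < 0) | (probs > 1)).any() or not np.isfinite(probs).all():
        bad = int(np.argmax((probs < 0) | (probs > 1) | ~np.isfinite(probs)))
        raise ValueError(f"probability outside [0,1] at position {bad}: {probs[bad]}")
    return probs, observed


def make_contingency(probs, observed, decision_threshold: float) -> ContingencyTable:
    """Tabulate warnings (prob >= threshold) against observed outcomes."""
    probs, observed = _validate(probs, observed)
    predicted = probs >= decision_threshold
    return ContingencyTable(
        hits=int(np.sum(predicted & observed)),
        misses=int(np.sum(~predicted & observed)),
        false_alarms=int(np.sum(predicted & ~observed)),
        correct_rejections=int(np.sum(~predicted & ~observed)),
    )


def metrics(
    table: ContingencyTable, decision_threshold: float | None = None
) -> VerificationMetrics:
    """Hit rate, false-alarm rate and proportion correct from a table."""
    if table.total == 0:
        raise ValueError("empty contingency table")
    pos = table.hits + table.misses
    neg = table.false_alarms + table.correct_rejections
    return VerificationMetrics(
        hit_rate=table.hits / pos if pos > 0 else None,
        false_alarm_rate=table.false_alarms / neg if neg > 0 else None,
        proportion_correct=(table.hits + table.correct_rejections) / table.total,
        decision_threshold=decision_threshold,
    )


def roc(probs, observed) -> ROCCurve:
    """ROC curve and score from per-region forecasts and outcomes.

    Decision thresholds sweep the unique forecast probabilities (descending,
    plus a sentinel above 1 that predicts nothing positive); points are
    augmented with (0,0) and (1,1) and integrated trapezoidally in order of
    increasing false-alarm rate. Requires at least one observed positive
    and one observed negative, otherwise the curve is undefined.
    """
    probs, observed = _validate(probs, observed)
    n_pos = int(observed.sum())
    n_neg = int((~observed).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            "ROC undefined: need at least one observed positive and one "
            f"observed negative (got {n_pos} positives, {n_neg} negatives)"
        )
    thresholds = np.concatenate([[np.inf], np.unique(probs)[::-1]])
    pts = []
    for th in thresholds:
        predicted = probs >= th
        hr = np.sum(predicted & observed) / n_pos
        far = np.sum(predicted & ~observed) / n_neg
        pts.append((far, hr))
    pts.append((1.0, 1.0))  # sentinel: everything predicted positive
    points = np.array(pts)
    order = np.lexsort((points[:, 1], points[:, 0]))
    points = points[order]
    auc = float(np.trapezoid(points[:, 1], points[:, 0]))
    return ROCCurve(points=points, auc=auc, thresholds=thresholds)


def verification_table(
    forecasts: pd.DataFrame,
    decision_thresholds=DEFAULT_DECISION_THRESHOLDS,
    scenario: str = "",
    threshold_level: float = 0.75,
) -> pd.DataFrame:
    """Summary table: one row per decision threshold with ROC score attached.

    ``forecasts`` needs columns ``exceedance_prob`` and ``observed_exceeds``
    (regions with a missing outcome are dropped). Undefined quantities —
    rates with empty denominators, or the ROC score when all outcomes agree
    — appear as NaN in the table rather than crashing the summary.
    """
    sub = forecasts.dropna(subset=["exceedance_prob", "observed_exceeds"])
    probs = sub["exceedance_prob"].to_numpy(dtype=float)
    observed = sub["observed_exceeds"].to_numpy(dtype=bool)
    try:
        auc = roc(probs, observed).auc
    except ValueError as exc:
        warnings.warn(f"ROC score undefined: {exc}", stacklevel=2)
        auc = np.nan
    rows = []
    for th in decision_thresholds:
        m = metrics(make_contingency(probs, observed, th), decision_threshold=th)
        rows.append(
            {
                "scenario": scenario,
                "threshold_level": threshold_level,
                "roc_score": auc,
                "decision_threshold": th,
                "hit_rate": np.nan if m.hit_rate is None else m.hit_rate,
                "false_alarm_rate": (
                    np.nan if m.false_alarm_rate is None else m.false_alarm_rate
                ),
                "proportion_correct": m.proportion_correct,
            }
        )
    return pd.DataFrame(rows)
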
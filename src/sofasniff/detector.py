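"""Delta-SOFA sepsis indication.

Under the Sepsis-3 convention, a rise of the SOFA total by >= 2 points
over the patient's baseline (delta-SOFA >= 2) indicates sepsis-related
organ dysfunction.  This module maintains the baseline, computes the
delta at every grid point, and emits the indicator states a surveillance
display consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Optional

from .config import EngineConfig
from .errors import InvalidInputError
from .scoring import Component, ComponentScore
from .timeline import EvaluationWindow, SofaScore, SofaSeries

__all__ = ["SepsisIndicator", "baseline_score", "delta_sofa", "indicator_series", "first_trigger"]


@dataclass(frozen=True)
class SepsisIndicator:
    """Indicator state at one grid instant."""

    patient_id: str
    eval_time: datetime
    baseline_total: int
    current_total: int
    delta: int
    triggered: bool

    def __post_init__(self) -> None:
        if self.delta != self.current_total - self.baseline_total:
            raise InvalidInputError("delta must equal current - baseline")


def _zero_score(patient_id: str, at: datetime, window_hours: float) -> SofaScore:
    window = EvaluationWindow(at - timedelta(hours=window_hours), at)
    comps = {c: ComponentScore(c, 0, missing=True) for c in Component}
    return SofaScore(patient_id, at, window, comps, 0)


def baseline_score(
    series: SofaSeries,
    policy: str = "first_window",
    config: EngineConfig = EngineConfig(),
    fixed: Optional[SofaScore] = None,
) -> SofaScore:
    """The reference SOFA score that deltas are measured against.

    Policies:

    - ``first_window``: the score at the first grid point whose 24-h
      window has fully elapsed since admission (falls back to the last
      grid point for stays shorter than one window);
    - ``assume_zero``: an all-zero score — no known prior organ
      dysfunction;
    - ``fixed``: a caller-provided score.
    """
    if not series.scores:
        raise InvalidInputError("cannot take a baseline from an empty series")
    if policy == "assume_zero":
        return _zero_score(series.patient_id, series.grid[0], config.window_hours)
    if policy == "fixed":
        if fixed is None:
            raise InvalidInputError("policy 'fixed' needs a provided baseline score")
        return fixed
    if policy != "first_window":
        raise InvalidInputError(f"unknown baseline policy {policy!r}")
    full = series.admission + timedelta(hours=config.window_hours)
    for s in series.scores:
        if s.eval_time >= full:
            return s
    return series.scores[-1]


def delta_sofa(current: SofaScore, baseline: SofaScore) -> int:
    """Current total minus baseline total (may be negative)."""
    return current.total - baseline.total


def indicator_series(
    series: SofaSeries,
    baseline: SofaScore,
    threshold: int = 2,
    latching: bool = False,
) -> list[SepsisIndicator]:
    """Indicator state at every grid point.

    Instantaneous mode (default): triggered wherever delta >= threshold.
    Latching mode: once triggered, stays triggered.
    """
    if threshold < 0:
        raise InvalidInputError("threshold must be >= 0")
    if baseline.patient_id != series.patient_id:
        raise InvalidInputError("baseline belongs to a different patient")
    out: list[SepsisIndicator] = []
    latched = False
    for s in series.scores:
        d = delta_sofa(s, baseline)
        hit = d >= threshold
        latched = latched or hit
        out.append(
            SepsisIndicator(
                series.patient_id,
                s.eval_time,
                baseline.total,
                s.total,
                d,
                latched if latching else hit,
            )
        )
    return out


def first_trigger(indicators: list[SepsisIndicator]) -> Optional[datetime]:
    """Earliest triggered grid instant, or None if never triggered."""
    for ind in indicators:
        if ind.triggered:
            return ind.eval_time
    return None
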
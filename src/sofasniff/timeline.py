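"""Rolling-window SOFA scoring over a patient's observation stream.

The engine recalculates the SOFA score on a clock-aligned grid (default
every 15 minutes).  Each recalculation looks at the trailing evaluation
window (default 24 hours, half-open ``(start, end]``) and takes, per organ
domain, the *most abnormal* value: every candidate observation snapshot in
the window is scored and the maximum component score wins.  When a domain
has no in-window data, the most recent older observation within that
variable's carry-forward age is used and flagged ``carried_forward``;
when nothing usable exists the domain is flagged ``missing``.

Multi-input domains (cardiovascular, respiratory, renal) form snapshots by
pairing each driver observation with the effective values of its co-inputs
at that instant — the latest co-input observation at or before the
snapshot, no older than its carry age.  PaO2 without a charted FiO2 is
assumed to be on room air (FiO2 0.21).  Urine output is the sum of
in-window increments and is treated as missing when the increments span
less than a configured fraction of the window.
"""

from __future__ import annotations

import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from typing import Iterable, NamedTuple, Optional, Sequence, Union

from . import scoring
from .config import EngineConfig
from .errors import InvalidInputError
from .scoring import Component, ComponentScore
from .variables import VARIABLES, is_boolean, validate_unit

__all__ = [
    "Observation",
    "EvaluationWindow",
    "SofaScore",
    "SofaSeries",
    "PatientTimeline",
    "Candidate",
    "recalculation_grid",
    "effective_observations",
    "compute_sofa_at",
    "compute_series",
]

_EPOCH = datetime(1970, 1, 1, tzinfo=timezone.utc)

#: driver variables per organ domain, in tie-break order
_DRIVERS: dict[Component, tuple[str, ...]] = {
    Component.RESPIRATORY: ("pf_ratio", "pao2"),
    Component.COAGULATION: ("platelets",),
    Component.LIVER: ("bilirubin",),
    Component.CARDIOVASCULAR: (
        "map",
        "dopamine_rate",
        "dobutamine_flag",
        "epinephrine_rate",
        "norepinephrine_rate",
    ),
    Component.CNS: ("gcs",),
    Component.RENAL: ("creatinine",),
}


def _require_aware(name: str, ts: datetime) -> None:
    if not isinstance(ts, datetime) or ts.tzinfo is None or ts.tzinfo.utcoffset(ts) is None:
        raise InvalidInputError(f"{name} must be a timezone-aware datetime, got {ts!r}")


@dataclass(frozen=True)
class Observation:
    """One time-stamped clinical measurement."""

    patient_id: str
    timestamp: datetime
    variable: str
    value: Union[float, bool]
    unit: str = ""

    def __post_init__(self) -> None:
        _require_aware("timestamp", self.timestamp)
        if self.variable not in VARIABLES:
            from .errors import UnknownVariableError

            raise UnknownVariableError(f"unknown variable {self.variable!r}")
        if self.unit:
            validate_unit(self.variable, self.unit)
        v = self.value
        if is_boolean(self.variable):
            if not isinstance(v, bool):
                raise InvalidInputError(
                    f"{self.variable} is a flag and needs a boolean value, got {v!r}"
                )
            return
        if isinstance(v, bool) or not isinstance(v, (int, float)) or not math.isfinite(v):
            raise InvalidInputError(f"{self.variable} needs a finite number, got {v!r}")
        if v < 0:
            raise InvalidInputError(f"{self.variable} must be >= 0, got {v!r}")
        if self.variable == "fio2" and not 0 < v <= 1.0:
            raise InvalidInputError(f"fio2 must be a fraction in (0, 1], got {v!r}")
        if self.variable == "gcs" and (v != int(v) or not 3 <= v <= 15):
            raise InvalidInputError(f"gcs must be an integer in [3, 15], got {v!r}")


@dataclass(frozen=True)
class EvaluationWindow:
    """Half-open trailing window ``(start, end]``."""

    start: datetime
    end: datetime

    def __post_init__(self) -> None:
        _require_aware("start", self.start)
        _require_aware("end", self.end)
        if self.end <= self.start:
            raise InvalidInputError("window end must be after start")

    @property
    def duration(self) -> timedelta:
        return self.end - self.start

    def contains(self, ts: datetime) -> bool:
        return self.start < ts <= self.end


class Candidate(NamedTuple):
    """One scoreable observation snapshot for a component."""

    timestamp: datetime
    value: Union[float, bool]
    carried: bool
    variable: str


@dataclass(frozen=True)
class SofaScore:
    """Six component scores and their total at one evaluation time."""

    patient_id: str
    eval_time: datetime
    window: EvaluationWindow
    components: dict[Component, ComponentScore]
    total: int

    def __post_init__(self) -> None:
        if self.eval_time != self.window.end:
            raise InvalidInputError("eval_time must equal window end")
        if self.total != sum(c.score for c in self.components.values()):
            raise InvalidInputError("total must equal the sum of component scores")


@dataclass
class SofaSeries:
    """SOFA scores on the recalculation grid for one patient."""

    patient_id: str
    admission: datetime
    grid: list[datetime]
    scores: list[SofaScore] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.grid) != len(self.scores):
            raise InvalidInputError("one score per grid point required")
        if len(self.grid) >= 2:
            steps = {self.grid[i + 1] - self.grid[i] for i in range(len(self.grid) - 1)}
            if len(steps) != 1 or min(steps) <= timedelta(0):
                raise InvalidInputError("grid must be strictly increasing with constant spacing")

    def totals(self) -> list[int]:
        return [s.total for s in self.scores]

    def __len__(self) -> int:
        return len(self.grid)


class PatientTimeline:
    """A patient's observations, indexed per variable and sorted by time."""

    def __init__(self, patient_id: str, observations: Iterable[Observation]):
        self.patient_id = patient_id
        self._ts: dict[str, list[datetime]] = {}
        self._vals: dict[str, list] = {}
        obs = sorted(observations, key=lambda o: o.timestamp)
        for o in obs:
            if o.patient_id != patient_id:
                raise InvalidInputError(
                    f"observation for {o.patient_id!r} in timeline of {patient_id!r}"
                )
            self._ts.setdefault(o.variable, []).append(o.timestamp)
            self._vals.setdefault(o.variable, []).append(o.value)
        self.n_observations = len(obs)
        self.first = obs[0].timestamp if obs else None
        self.last = obs[-1].timestamp if obs else None

    @classmethod
    def from_observations(cls, observations: Sequence[Observation]) -> "PatientTimeline":
        if not observations:
            raise InvalidInputError("cannot infer patient id from an empty stream")
        return cls(observations[0].patient_id, observations)

    def stream(self, variable: str) -> tuple[list[datetime], list]:
        return self._ts.get(variable, []), self._vals.get(variable, [])

    # -- lookup primitives -------------------------------------------------

    def candidates(
        self, variable: str, window: EvaluationWindow, carry_max_age: timedelta
    ) -> list[Candidate]:
        """Scoreable values for one variable in one window.

        All in-window observations when any exist; otherwise the most
        recent older observation within ``carry_max_age`` of the window
        end, flagged carried; otherwise nothing.
        """
        ts, vals = self.stream(variable)
        lo = bisect_right(ts, window.start)
        hi = bisect_right(ts, window.end)
        if hi > lo:
            return [Candidate(ts[i], vals[i], False, variable) for i in range(lo, hi)]
        if lo > 0 and window.end - ts[lo - 1] <= carry_max_age:
            return [Candidate(ts[lo - 1], vals[lo - 1], True, variable)]
        return []

    def value_at(
        self, variable: str, instant: datetime, carry_max_age: timedelta
    ):
        """Latest observation at or before ``instant`` within its carry age."""
        ts, vals = self.stream(variable)
        i = bisect_right(ts, instant)
        if i > 0 and instant - ts[i - 1] <= carry_max_age:
            return vals[i - 1]
        return None

    def closest_within(
        self, variable: str, instant: datetime, tolerance: timedelta, not_after: datetime
    ):
        """Observation of ``variable`` temporally closest to ``instant``.

        Only observations at or before ``not_after`` (the evaluation time)
        are eligible; ties go to the earlier observation.
        """
        ts, vals = self.stream(variable)
        hi = bisect_right(ts, not_after)
        if hi == 0:
            return None
        i = bisect_left(ts, instant, 0, hi)
        best = None
        best_dt = None
        for j in (i - 1, i):
            if 0 <= j < hi:
                dt = abs(ts[j] - instant)
                if dt <= tolerance and (best_dt is None or dt < best_dt):
                    best, best_dt = vals[j], dt
        return best


def recalculation_grid(
    admission: datetime, end: datetime, interval: timedelta = timedelta(minutes=15)
) -> list[datetime]:
    """Clock-aligned recalculation instants in ``[admission, end]``.

    Instants are whole multiples of ``interval`` on the UTC clock (so a
    15-minute interval lands on :00/:15/:30/:45); the first grid point is
    the first aligned instant at or after admission.
    """
    _require_aware("admission", admission)
    _require_aware("end", end)
    if end <= admission:
        raise InvalidInputError("end must be after admission")
    if interval <= timedelta(0):
        raise InvalidInputError("interval must be positive")
    step_us = interval // timedelta(microseconds=1)
    adm_us = (admission - _EPOCH) // timedelta(microseconds=1)
    end_us = (end - _EPOCH) // timedelta(microseconds=1)
    first_us = -(-adm_us // step_us) * step_us  # ceil to the aligned grid
    tz = admission.tzinfo
    return [
        (_EPOCH + timedelta(microseconds=us)).astimezone(tz)
        for us in range(first_us, end_us + 1, step_us)
    ]


def effective_observations(
    timeline: PatientTimeline,
    variable: str,
    window: EvaluationWindow,
    carry_max_age: timedelta,
) -> list[Candidate]:
    """In-window observations of a variable, or its carried fallback.

    Returns all in-window observations (``carried=False``); failing that,
    the most recent observation no older than ``carry_max_age`` relative
    to the window end (``carried=True``); failing that, an empty list.
    """
    return timeline.candidates(variable, window, carry_max_age)


# ---------------------------------------------------------------------------
# component evaluators
# ---------------------------------------------------------------------------


def _carry(config: EngineConfig, variable: str) -> timedelta:
    return timedelta(hours=config.carry_hours(variable))


def _pick_best(scored: list[tuple[int, Candidate]]) -> tuple[int, Candidate]:
    """Maximum score; among maxima the earliest snapshot, then driver order."""
    best_score = max(s for s, _ in scored)
    achieving = [c for s, c in scored if s == best_score]
    achieving.sort(key=lambda c: c.timestamp)
    return best_score, achieving[0]


def _single_input(
    component: Component,
    timeline: PatientTimeline,
    window: EvaluationWindow,
    config: EngineConfig,
    score_fn,
) -> Optional[ComponentScore]:
    (variable,) = _DRIVERS[component]
    cands = timeline.candidates(variable, window, _carry(config, variable))
    if not cands:
        return None
    scored = [(score_fn(c.value), c) for c in cands]
    score, src = _pick_best(scored)
    return ComponentScore(
        component, score, src.value, src.timestamp, src.variable, src.carried, False
    )


def _eval_respiratory(
    timeline: PatientTimeline, window: EvaluationWindow, config: EngineConfig
) -> Optional[ComponentScore]:
    tol = timedelta(minutes=config.pairing_tolerance_minutes)
    cands: list[Candidate] = list(
        timeline.candidates("pf_ratio", window, _carry(config, "pf_ratio"))
    )
    for c in timeline.candidates("pao2", window, _carry(config, "pao2")):
        fio2 = timeline.closest_within("fio2", c.timestamp, tol, window.end)
        if fio2 is None:
            fio2 = config.room_air_fio2
        cands.append(Candidate(c.timestamp, c.value / fio2, c.carried, "pf_ratio"))
    if not cands:
        return None
    support_age = _carry(config, "respiratory_support_flag")
    scored = []
    for c in cands:
        support = timeline.value_at("respiratory_support_flag", c.timestamp, support_age)
        scored.append((scoring.score_respiratory(c.value, bool(support)), c))
    score, src = _pick_best(scored)
    return ComponentScore(
        Component.RESPIRATORY, score, src.value, src.timestamp, src.variable, src.carried, False
    )


def _eval_cardiovascular(
    timeline: PatientTimeline, window: EvaluationWindow, config: EngineConfig
) -> Optional[ComponentScore]:
    drivers = _DRIVERS[Component.CARDIOVASCULAR]
    all_cands: list[Candidate] = []
    for var in drivers:
        all_cands.extend(timeline.candidates(var, window, _carry(config, var)))
    if not all_cands:
        return None
    scored = []
    for c in all_cands:
        inputs = {}
        for var in drivers:
            if var == c.variable:
                inputs[var] = c.value
            else:
                inputs[var] = timeline.value_at(var, c.timestamp, _carry(config, var))
        map_mmhg = inputs["map"] if inputs["map"] is not None else 75.0
        s = scoring.score_cardiovascular(
            map_mmhg,
            inputs["dopamine_rate"] or 0.0,
            bool(inputs["dobutamine_flag"]),
            inputs["epinephrine_rate"] or 0.0,
            inputs["norepinephrine_rate"] or 0.0,
        )
        scored.append((s, c))
    score, src = _pick_best(scored)
    return ComponentScore(
        Component.CARDIOVASCULAR, score, src.value, src.timestamp, src.variable, src.carried, False
    )


def _urine_total(
    timeline: PatientTimeline, window: EvaluationWindow, config: EngineConfig
) -> Optional[float]:
    """Windowed urine output, or None when coverage is insufficient.

    Increments are attributed to their timestamps; coverage is the span
    from the first to the last in-window increment relative to the window
    duration (a single increment has zero coverage).
    """
    ts, vals = timeline.stream("urine_output_increment")
    lo = bisect_right(ts, window.start)
    hi = bisect_right(ts, window.end)
    if hi - lo < 2:
        return None
    coverage = (ts[hi - 1] - ts[lo]) / window.duration
    if coverage < config.urine_coverage_fraction:
        return None
    return float(sum(vals[lo:hi]))


def _eval_renal(
    timeline: PatientTimeline, window: EvaluationWindow, config: EngineConfig
) -> Optional[ComponentScore]:
    cands = timeline.candidates("creatinine", window, _carry(config, "creatinine"))
    scored = [(scoring.score_renal(c.value, None), c) for c in cands]
    urine = _urine_total(timeline, window, config)
    if urine is not None:
        # oliguria thresholds are per 24 h; scale for other window lengths
        f = window.duration / timedelta(hours=24)
        if urine < 200 * f:
            uscore = 4
        elif urine < 500 * f:
            uscore = 3
        else:
            uscore = 0
        scored.append((uscore, Candidate(window.end, urine, False, "urine_output_24h")))
    if not scored:
        return None
    score, src = _pick_best(scored)
    return ComponentScore(
        Component.RENAL, score, src.value, src.timestamp, src.variable, src.carried, False
    )


def _evaluate_component(
    component: Component,
    timeline: PatientTimeline,
    window: EvaluationWindow,
    config: EngineConfig,
) -> Optional[ComponentScore]:
    if component is Component.RESPIRATORY:
        return _eval_respiratory(timeline, window, config)
    if component is Component.COAGULATION:
        return _single_input(component, timeline, window, config, scoring.score_coagulation)
    if component is Component.LIVER:
        return _single_input(component, timeline, window, config, scoring.score_liver)
    if component is Component.CARDIOVASCULAR:
        return _eval_cardiovascular(timeline, window, config)
    if component is Component.CNS:
        return _single_input(
            component, timeline, window, config, lambda v: scoring.score_cns(int(v))
        )
    return _eval_renal(timeline, window, config)


def compute_sofa_at(
    timeline: PatientTimeline, t: datetime, config: EngineConfig = EngineConfig()
) -> SofaScore:
    """Score all six organ domains for the window ending at ``t``."""
    _require_aware("t", t)
    window = EvaluationWindow(t - timedelta(hours=config.window_hours), t)
    components: dict[Component, ComponentScore] = {}
    for component in Component:
        cs = _evaluate_component(component, timeline, window, config)
        if cs is None:
            cs = ComponentScore(component, config.missing_score, missing=True)
        components[component] = cs
    total = sum(c.score for c in components.values())
    return SofaScore(timeline.patient_id, t, window, components, total)


def compute_series(
    timeline: PatientTimeline,
    config: EngineConfig = EngineConfig(),
    admission: Optional[datetime] = None,
    end: Optional[datetime] = None,
) -> SofaSeries:
    """SOFA scores at every grid instant between admission and end.

    ``admission`` and ``end`` default to the first and last observation.
    Under the ``carry_component`` missing policy, a component with no
    usable data repeats the previous grid point's component score (still
    flagged missing, with the inherited provenance).
    """
    admission = admission if admission is not None else timeline.first
    end = end if end is not None else timeline.last
    if admission is None or end is None:
        raise InvalidInputError("timeline is empty and no explicit span was given")
    grid = recalculation_grid(admission, end, timedelta(minutes=config.grid_minutes))
    scores: list[SofaScore] = []
    prev: Optional[SofaScore] = None
    for t in grid:
        s = compute_sofa_at(timeline, t, config)
        if config.missing_policy == "carry_component" and prev is not None:
            patched = dict(s.components)
            changed = False
            for comp, cs in patched.items():
                if cs.missing:
                    prior = prev.components[comp]
                    if not prior.missing or prior.score != cs.score:
                        patched[comp] = ComponentScore(
                            comp,
                            prior.score,
                            None,
                            None,
                            prior.source_variable,
                            True,
                            True,
                        )
                        changed = True
            if changed:
                total = sum(c.score for c in patched.values())
                s = SofaScore(s.patient_id, s.eval_time, s.window, patched, total)
        scores.append(s)
        prev = s
    return SofaSeries(timeline.patient_id, admission, grid, scores)
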
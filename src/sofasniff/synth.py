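"""Synthetic ICU observation streams.

Generates reproducible per-patient observation timelines with realistic
charting cadence — labs roughly daily, vitals roughly hourly, blood gases
every few hours, urine output charted hourly — plus injectable
organ-failure trajectories.  A failure event names an organ domain, an
onset hour, a target severity (the SOFA component score 0-4) and a ramp
duration; the generator guarantees that the relevant raw variables sit
inside the target severity's scoring band from the end of the ramp
onward, while during the ramp the variables deteriorate gradually but
stay at severity <= 1, so a downstream threshold crossing is attributable
to ramp completion.

Values are drawn as clipped Gaussians around band representatives so that
charting noise never crosses a scoring cut-point.  Everything is
deterministic for a fixed seed; cohort members get per-patient seeds
derived from the base seed by a splitmix64 mix of ``base + index + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta, timezone
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import InvalidInputError
from .scoring import Component
from .timeline import Observation

__all__ = [
    "FailureEvent",
    "TrajectorySpec",
    "generate_patient",
    "generate_cohort",
    "cohort_specs",
    "make_sepsis_cohort",
    "derive_seed",
]

_M64 = (1 << 64) - 1


def _splitmix64(x: int) -> int:
    x = (x + 0x9E3779B97F4A7C15) & _M64
    z = x
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _M64
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _M64
    return (z ^ (z >> 31)) & _M64


def derive_seed(base_seed: int, index: int) -> int:
    """Stable per-patient seed: splitmix64 of ``base + index + 1``, mod 2^31."""
    return _splitmix64((base_seed & _M64) + index + 1) % (1 << 31)


@dataclass(frozen=True)
class FailureEvent:
    """One injected organ-failure trajectory."""

    component: Component
    onset_hour: float
    target_score: int
    ramp_hours: float = 6.0

    def __post_init__(self) -> None:
        if self.target_score not in (0, 1, 2, 3, 4):
            raise InvalidInputError("target_score must be 0-4")
        if self.onset_hour < 0:
            raise InvalidInputError("onset_hour must be >= 0")
        if self.ramp_hours <= 0:
            raise InvalidInputError("ramp_hours must be > 0")

    @property
    def complete_hour(self) -> float:
        return self.onset_hour + self.ramp_hours


@dataclass(frozen=True)
class TrajectorySpec:
    """Everything needed to synthesize one patient's stream."""

    patient_id: str = "P0001"
    stay_hours: float = 72.0
    seed: int = 0
    admission: datetime = datetime(2024, 3, 1, 8, 0, tzinfo=timezone.utc)
    lab_interval_hours: float = 24.0
    lab_jitter_hours: float = 2.0
    vital_interval_hours: float = 1.0
    vital_jitter_hours: float = 1.0 / 6.0
    gas_interval_hours: float = 6.0
    gas_jitter_hours: float = 0.5
    urine_interval_hours: float = 1.0
    failure_interval_hours: float = 2.0
    emit_support_flag: bool = True
    failures: tuple[FailureEvent, ...] = ()

    def __post_init__(self) -> None:
        if self.stay_hours <= 0:
            raise InvalidInputError("stay_hours must be > 0")
        for name in (
            "lab_interval_hours",
            "vital_interval_hours",
            "gas_interval_hours",
            "urine_interval_hours",
            "failure_interval_hours",
        ):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be > 0")
        object.__setattr__(self, "failures", tuple(self.failures))
        seen = set()
        for ev in self.failures:
            if ev.component in seen:
                raise InvalidInputError(f"multiple failure events for {ev.component.value}")
            seen.add(ev.component)
            if ev.onset_hour >= self.stay_hours:
                raise InvalidInputError("failure onset must precede the end of the stay")
            if ev.component is Component.RESPIRATORY and ev.target_score >= 3:
                if not self.emit_support_flag:
                    raise InvalidInputError(
                        "respiratory severity >= 3 requires the support flag to be emitted"
                    )

    def event_for(self, component: Component) -> Optional[FailureEvent]:
        for ev in self.failures:
            if ev.component is component:
                return ev
        return None


# scoring bands per variable: score -> (representative, clip_lo, clip_hi, noise_sd)
# bounds sit strictly inside the cut-points so clipped noise cannot change the score
_PF_BANDS = {
    0: (460.0, 405.0, 520.0, 12.0),
    1: (350.0, 305.0, 395.0, 10.0),
    2: (250.0, 205.0, 295.0, 10.0),
    3: (150.0, 103.0, 195.0, 10.0),
    4: (70.0, 40.0, 96.0, 8.0),
}
_PLT_BANDS = {
    0: (250.0, 155.0, 340.0, 20.0),
    1: (125.0, 103.0, 147.0, 6.0),
    2: (75.0, 52.0, 97.0, 6.0),
    3: (34.0, 21.0, 48.0, 4.0),
    4: (10.0, 2.0, 18.0, 3.0),
}
_BILI_BANDS = {
    0: (0.6, 0.1, 1.1, 0.15),
    1: (1.6, 1.25, 1.95, 0.1),
    2: (3.5, 2.05, 5.9, 0.4),
    3: (8.0, 6.05, 11.9, 0.7),
    4: (14.0, 12.1, 20.0, 1.0),
}
_MAP_BANDS = {0: (82.0, 72.0, 96.0, 4.0), 1: (62.0, 52.0, 68.0, 3.0)}
_CREAT_BANDS = {
    0: (0.8, 0.4, 1.15, 0.1),
    1: (1.6, 1.25, 1.95, 0.1),
    2: (2.7, 2.05, 3.45, 0.2),
    3: (4.2, 3.55, 4.95, 0.2),
    4: (6.5, 5.1, 9.0, 0.5),
}
_GCS_BANDS = {0: (15, 15), 1: (13, 14), 2: (10, 12), 3: (6, 9), 4: (3, 5)}
_NOREPI = {3: (0.06, 0.02, 0.095, 0.01), 4: (0.3, 0.12, 0.5, 0.04)}
_DOPA = {2: (3.0, 1.0, 4.8, 0.5)}

_FAILURE_FIO2 = 0.6
_ROOM_AIR = 0.21


def _band_value(rng: np.random.Generator, bands: Mapping[int, tuple], score: int) -> float:
    rep, lo, hi, sd = bands[score]
    return float(np.clip(rng.normal(rep, sd), lo, hi))


def _ramp_value(
    rng: np.random.Generator, bands: Mapping[int, tuple], hold: int, progress: float
) -> float:
    """Value deteriorating from the normal band toward the severity-``hold``
    band, clipped so the score never exceeds ``hold``."""
    rep0, lo0, hi0, sd0 = bands[0]
    rep1, lo1, hi1, sd1 = bands[hold]
    rep = rep0 + (rep1 - rep0) * progress
    lo, hi = (min(lo0, lo1), max(hi0, hi1))
    # asymmetric clip: never worse than the hold band allows
    if rep1 < rep0:  # lower is worse
        lo = lo1
    else:
        hi = hi1
    return float(np.clip(rng.normal(rep, min(sd0, sd1)), lo, hi))


def _severity_at(event: Optional[FailureEvent], hour: float) -> tuple[int, float]:
    """(severity band to emit, ramp progress in [0,1]) at a stay hour."""
    if event is None or hour < event.onset_hour or event.target_score == 0:
        return 0, 0.0
    if hour >= event.complete_hour:
        return event.target_score, 1.0
    progress = (hour - event.onset_hour) / event.ramp_hours
    return min(1, event.target_score), progress


def _sample_hours(
    rng: np.random.Generator,
    spec: TrajectorySpec,
    interval: float,
    jitter: float,
    first: float,
    event: Optional[FailureEvent] = None,
) -> list[float]:
    """Charting times: the routine cadence, densified during a failure."""
    hours: list[float] = []
    t = first
    while t < spec.stay_hours:
        hours.append(t)
        t += interval + (jitter * float(rng.uniform(-1.0, 1.0)) if jitter > 0 else 0.0)
        t = max(t, hours[-1] + 1.0 / 60.0)
    if event is not None and event.target_score > 0:
        t = event.onset_hour
        while t < spec.stay_hours:
            hours.append(t)
            t += spec.failure_interval_hours
        if event.complete_hour < spec.stay_hours:
            hours.append(event.complete_hour)
    return sorted(set(round(h, 6) for h in hours))


def generate_patient(spec: TrajectorySpec) -> list[Observation]:
    """Synthesize one patient's observation stream (sorted by time)."""
    rng = np.random.default_rng(spec.seed)
    at = lambda h: spec.admission + timedelta(hours=h)
    obs: list[Observation] = []

    def emit(hour: float, variable: str, value, unit: str) -> None:
        obs.append(Observation(spec.patient_id, at(hour), variable, value, unit))

    # respiratory: PaO2 (with FiO2 + support flag once severity needs them)
    ev = spec.event_for(Component.RESPIRATORY)
    on_support = ev is not None and ev.target_score >= 3
    if spec.emit_support_flag:
        emit(0.0, "respiratory_support_flag", False, "bool")
    for h in _sample_hours(rng, spec, spec.gas_interval_hours, spec.gas_jitter_hours, 0.25, ev):
        sev, prog = _severity_at(ev, h)
        pf = (
            _band_value(rng, _PF_BANDS, sev)
            if sev == 0 or prog >= 1.0
            else _ramp_value(rng, _PF_BANDS, sev, prog)
        )
        failing = ev is not None and h >= ev.onset_hour
        fio2 = _FAILURE_FIO2 if (on_support and failing) else _ROOM_AIR
        emit(h, "pao2", round(pf * fio2, 1), "mmHg")
        if on_support and failing:
            emit(h, "fio2", fio2, "fraction")
            emit(h, "respiratory_support_flag", True, "bool")

    # single-lab domains
    for comp, var, bands, unit, digits in (
        (Component.COAGULATION, "platelets", _PLT_BANDS, "10^3/uL", 0),
        (Component.LIVER, "bilirubin", _BILI_BANDS, "mg/dL", 2),
        (Component.RENAL, "creatinine", _CREAT_BANDS, "mg/dL", 2),
    ):
        ev = spec.event_for(comp)
        for h in _sample_hours(
            rng, spec, spec.lab_interval_hours, spec.lab_jitter_hours, 0.5, ev
        ):
            sev, prog = _severity_at(ev, h)
            v = (
                _band_value(rng, bands, sev)
                if sev == 0 or prog >= 1.0
                else _ramp_value(rng, bands, sev, prog)
            )
            emit(h, var, round(v, digits), unit)

    # cardiovascular: MAP hourly; vasoactive infusions once the ramp completes
    ev = spec.event_for(Component.CARDIOVASCULAR)
    for h in _sample_hours(
        rng, spec, spec.vital_interval_hours, spec.vital_jitter_hours, 0.1, ev
    ):
        sev, _ = _severity_at(ev, h)
        emit(h, "map", round(_band_value(rng, _MAP_BANDS, min(sev, 1)), 1), "mmHg")
    if ev is not None and ev.target_score >= 2:
        h = ev.complete_hour
        while h < spec.stay_hours:
            if ev.target_score == 2:
                emit(h, "dopamine_rate", round(_band_value(rng, _DOPA, 2), 2), "ug/kg/min")
            else:
                emit(
                    h,
                    "norepinephrine_rate",
                    round(_band_value(rng, _NOREPI, ev.target_score), 3),
                    "ug/kg/min",
                )
            h += min(0.75, spec.vital_interval_hours)

    # CNS: GCS hourly (integers within the severity band)
    ev = spec.event_for(Component.CNS)
    for h in _sample_hours(
        rng, spec, spec.vital_interval_hours, spec.vital_jitter_hours, 0.15, ev
    ):
        sev, _ = _severity_at(ev, h)
        lo, hi = _GCS_BANDS[sev]
        emit(h, "gcs", int(rng.integers(lo, hi + 1)), "points")

    # urine output increments, charted hourly
    h = 1.0
    while h < spec.stay_hours:
        emit(h, "urine_output_increment", round(float(np.clip(rng.normal(70, 10), 40, 120)), 0), "mL")
        h += spec.urine_interval_hours

    obs.sort(key=lambda o: (o.timestamp, o.variable))
    return obs


def cohort_specs(
    n: int,
    base_spec: Optional[TrajectorySpec] = None,
    seed: int = 0,
    failures_by_patient: Optional[Mapping[int, Sequence[FailureEvent]]] = None,
) -> list[TrajectorySpec]:
    """Per-patient specs with derived seeds and ids ``P0001..P{n:04d}``."""
    if n < 1:
        raise InvalidInputError("cohort size must be >= 1")
    base = base_spec if base_spec is not None else TrajectorySpec()
    failures_by_patient = failures_by_patient or {}
    specs = []
    for i in range(n):
        specs.append(
            replace(
                base,
                patient_id=f"P{i + 1:04d}",
                seed=derive_seed(seed, i),
                failures=tuple(failures_by_patient.get(i, base.failures)),
            )
        )
    return specs


def generate_cohort(
    n: int,
    base_spec: Optional[TrajectorySpec] = None,
    seed: int = 0,
    failures_by_patient: Optional[Mapping[int, Sequence[FailureEvent]]] = None,
) -> list[list[Observation]]:
    """Observation streams for a reproducible cohort of ``n`` patients."""
    return [generate_patient(s) for s in cohort_specs(n, base_spec, seed, failures_by_patient)]


def make_sepsis_cohort(
    n: int,
    fraction: float = 0.2,
    seed: int = 0,
    base_spec: Optional[TrajectorySpec] = None,
    onset_hour: float = 30.0,
    ramp_hours: float = 4.0,
    target_score: int = 3,
) -> tuple[list[list[Observation]], list[int]]:
    """Cohort in which a deterministic subset develops organ failure.

    ``round(fraction * n)`` patients are assigned a single-domain failure
    reaching ``target_score`` (a delta-SOFA of ``target_score`` over an
    all-normal baseline) with onset after the first full evaluation
    window.  Returns the streams and the assigned patient indices.
    """
    if not 0 <= fraction <= 1:
        raise InvalidInputError("fraction must be in [0, 1]")
    base = base_spec if base_spec is not None else TrajectorySpec(stay_hours=48.0)
    k = round(fraction * n)
    rng = np.random.default_rng(derive_seed(seed, 10_000))
    assigned = sorted(rng.choice(n, size=k, replace=False).tolist()) if k else []
    domains = [
        Component.COAGULATION,
        Component.LIVER,
        Component.CNS,
        Component.CARDIOVASCULAR,
        Component.RENAL,
        Component.RESPIRATORY,
    ]
    failures = {
        idx: [FailureEvent(domains[j % len(domains)], onset_hour, target_score, ramp_hours)]
        for j, idx in enumerate(assigned)
    }
    return generate_cohort(n, base, seed, failures), assigned
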
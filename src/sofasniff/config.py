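"""Run configuration: every tunable of the scoring engine and detector.

Defaults reproduce the deployed scheme: a 24-hour worst-value window
recalculated on a 15-minute grid, with sepsis indicated at delta-SOFA >= 2
versus baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping, Optional

import yaml

from .errors import ConfigError
from .variables import VARIABLES, staleness_class

#: default maximum carry-forward age, in hours, per staleness class
DEFAULT_CARRY_HOURS: dict[str, float] = {
    "labs": 48.0,
    "vitals": 4.0,
    "rates": 1.0,
    "status": 24.0,
}

MISSING_POLICIES = ("zero", "carry_component")
BASELINE_POLICIES = ("first_window", "assume_zero", "fixed")


@dataclass(frozen=True)
class EngineConfig:
    """All tunables of the timeline engine and sepsis detector.

    Attributes
    ----------
    window_hours : float
        Length of the trailing worst-value window (default 24).
    grid_minutes : float
        Recalculation interval; grid instants are clock-aligned multiples
        of this interval (default 15).
    carry_max_age_hours : mapping
        Per staleness class ("labs", "vitals", "rates", "status"): how
        long past the window an observation may be carried forward.
    carry_overrides_hours : mapping
        Optional per-variable overrides of the class defaults.
    missing_policy : str
        "zero": a component with no usable data scores ``missing_score``;
        "carry_component": it repeats the previous grid point's component
        score (still flagged missing).
    missing_score : int
        Score assigned to a missing component under the "zero" policy.
    urine_coverage_fraction : float
        Minimum fraction of the window that urine-output increments must
        span for the windowed urine total to be usable.
    pairing_tolerance_minutes : float
        Maximum time separation when pairing a PaO2 with an FiO2
        observation to form a P/F ratio.
    room_air_fio2 : float
        FiO2 assumed when PaO2 is present but no FiO2 is charted.
    baseline_policy : str
        "first_window" (default), "assume_zero", or "fixed".
    delta_threshold : int
        Delta-SOFA that indicates sepsis-related organ dysfunction.
    latching : bool
        False (default): the indicator reflects the instantaneous delta;
        True: once triggered it stays triggered.
    """

    window_hours: float = 24.0
    grid_minutes: float = 15.0
    carry_max_age_hours: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CARRY_HOURS)
    )
    carry_overrides_hours: Mapping[str, float] = field(default_factory=dict)
    missing_policy: str = "zero"
    missing_score: int = 0
    urine_coverage_fraction: float = 0.5
    pairing_tolerance_minutes: float = 60.0
    room_air_fio2: float = 0.21
    baseline_policy: str = "first_window"
    delta_threshold: int = 2
    latching: bool = False

    def __post_init__(self) -> None:
        if self.window_hours <= 0:
            raise ConfigError("window_hours must be > 0")
        if self.grid_minutes <= 0:
            raise ConfigError("grid_minutes must be > 0")
        if self.missing_policy not in MISSING_POLICIES:
            raise ConfigError(f"missing_policy must be one of {MISSING_POLICIES}")
        if self.baseline_policy not in BASELINE_POLICIES:
            raise ConfigError(f"baseline_policy must be one of {BASELINE_POLICIES}")
        if self.missing_score not in (0, 1, 2, 3, 4):
            raise ConfigError("missing_score must be in 0..4")
        if not 0 <= self.urine_coverage_fraction <= 1:
            raise ConfigError("urine_coverage_fraction must be in [0, 1]")
        if self.delta_threshold < 0:
            raise ConfigError("delta_threshold must be >= 0")
        for cls in self.carry_max_age_hours:
            if cls not in DEFAULT_CARRY_HOURS:
                raise ConfigError(f"unknown staleness class {cls!r}")
        for var in self.carry_overrides_hours:
            if var not in VARIABLES:
                raise ConfigError(f"carry override names unknown variable {var!r}")

    def carry_hours(self, variable: str) -> float:
        """Maximum carry-forward age (hours) for one variable."""
        if variable in self.carry_overrides_hours:
            return float(self.carry_overrides_hours[variable])
        cls = staleness_class(variable)
        return float(self.carry_max_age_hours.get(cls, DEFAULT_CARRY_HOURS[cls]))

    def with_updates(self, **kwargs: Any) -> "EngineConfig":
        return replace(self, **kwargs)


def load_config(path: str | Path, **overrides: Any) -> EngineConfig:
    """Load an :class:`EngineConfig` from a YAML (or JSON) file.

    Unknown keys are rejected.  Keyword overrides win over file values.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    known = set(EngineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    raw.update(overrides)
    try:
        return EngineConfig(**raw)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def dump_config(config: EngineConfig, path: Optional[str | Path] = None) -> str:
    """Serialize a config to YAML; optionally write it to ``path``."""
    data = {
        k: (dict(v) if isinstance(v, Mapping) else v)
        for k, v in config.__dict__.items()
    }
    text = yaml.safe_dump(data, sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text
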
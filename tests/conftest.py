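from __future__ import annotations

from datetime import datetime, timedelta, timezone

import pytest

from sofasniff.config import EngineConfig
from sofasniff.timeline import Observation, PatientTimeline

T0 = datetime(2024, 3, 1, 0, 0, tzinfo=timezone.utc)


def ts(hours: float) -> datetime:
    """Instant ``hours`` after the reference admission time."""
    return T0 + timedelta(hours=hours)


def obs(variable: str, hours: float, value, patient_id: str = "P1") -> Observation:
    return Observation(patient_id, ts(hours), variable, value)


@pytest.fixture
def config() -> EngineConfig:
    return EngineConfig()


@pytest.fixture
def timeline_factory():
    def make(observations, patient_id: str = "P1") -> PatientTimeline:
        return PatientTimeline(patient_id, observations)

    return make
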
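"""SOFA component scoring.

Pure functions mapping raw physiologic measurements to the six SOFA
organ-domain subscores (each 0-4) and their total (0-24), following the
original sequential organ failure assessment definition:

===============  ==========================================================
Component        Measurement
===============  ==========================================================
respiratory      PaO2/FiO2 ratio (mmHg), with/without respiratory support
coagulation      platelet count (x10^3/uL)
liver            total bilirubin (mg/dL)
cardiovascular   mean arterial pressure (mmHg) and vasopressor doses
                 (ug/kg/min for dopamine/epinephrine/norepinephrine;
                 dobutamine at any dose)
cns              Glasgow Coma Scale (3-15)
renal            serum creatinine (mg/dL) and/or 24-h urine output (mL)
===============  ==========================================================

Respiratory scores 3 and 4 additionally require the patient to be on
respiratory support; without support the respiratory score saturates at 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime
from enum import Enum
from typing import Optional, Union

from .errors import InvalidInputError

__all__ = [
    "Component",
    "ComponentScore",
    "score_respiratory",
    "score_coagulation",
    "score_liver",
    "score_cardiovascular",
    "score_cns",
    "score_renal",
    "total_sofa",
]


class Component(str, Enum):
    """The six SOFA organ domains."""

    RESPIRATORY = "respiratory"
    COAGULATION = "coagulation"
    LIVER = "liver"
    CARDIOVASCULAR = "cardiovascular"
    CNS = "cns"
    RENAL = "renal"


COMPONENTS: tuple[Component, ...] = tuple(Component)


@dataclass(frozen=True)
class ComponentScore:
    """One organ-domain subscore with provenance.

    Attributes
    ----------
    component : Component
    score : int
        0 (normal) to 4 (most abnormal).
    source_value : float or bool or None
        The raw measurement that produced the score (None when missing).
    source_timestamp : datetime or None
        When that measurement was taken.
    source_variable : str or None
        Which observed variable drove the score (e.g. ``"platelets"``,
        ``"norepinephrine_rate"``, ``"urine_output_24h"``).
    carried_forward : bool
        True when the source observation predates the evaluation window
        and was carried forward.
    missing : bool
        True when no usable data existed; the score is then the configured
        missing-data score (default 0) and the source fields are None.
    """

    component: Component
    score: int
    source_value: Optional[Union[float, bool]] = None
    source_timestamp: Optional[datetime] = None
    source_variable: Optional[str] = None
    carried_forward: bool = False
    missing: bool = False

    def __post_init__(self) -> None:
        if self.score not in (0, 1, 2, 3, 4):
            raise InvalidInputError(f"component score must be 0-4, got {self.score}")
        if self.missing and self.source_timestamp is not None:
            raise InvalidInputError("missing component cannot carry a source timestamp")


def _check_finite_nonneg(name: str, value: float) -> None:
    if not math.isfinite(value) or value < 0:
        raise InvalidInputError(f"{name} must be finite and >= 0, got {value!r}")


def score_respiratory(pf_ratio: float, respiratory_support: bool) -> int:
    """Score the respiratory domain from the PaO2/FiO2 ratio (mmHg).

    Scores 3 and 4 require respiratory support (mechanical ventilation or
    equivalent); without support the score is capped at 2 even for a ratio
    below 200.
    """
    if not math.isfinite(pf_ratio) or pf_ratio <= 0:
        raise InvalidInputError(f"PaO2/FiO2 ratio must be finite and > 0, got {pf_ratio!r}")
    if pf_ratio >= 400:
        return 0
    if pf_ratio >= 300:
        return 1
    if pf_ratio >= 200 or not respiratory_support:
        return 2
    if pf_ratio >= 100:
        return 3
    return 4


def score_coagulation(platelets: float) -> int:
    """Score the coagulation domain from the platelet count (x10^3/uL)."""
    _check_finite_nonneg("platelets", platelets)
    if platelets >= 150:
        return 0
    if platelets >= 100:
        return 1
    if platelets >= 50:
        return 2
    if platelets >= 20:
        return 3
    return 4


def score_liver(bilirubin: float) -> int:
    """Score the liver domain from total bilirubin (mg/dL)."""
    _check_finite_nonneg("bilirubin", bilirubin)
    if bilirubin < 1.2:
        return 0
    if bilirubin < 2.0:
        return 1
    if bilirubin < 6.0:
        return 2
    if bilirubin < 12.0:
        return 3
    return 4


def score_cardiovascular(
    map_mmhg: float,
    dopamine: float = 0.0,
    dobutamine_any: bool = False,
    epinephrine: float = 0.0,
    norepinephrine: float = 0.0,
) -> int:
    """Score the cardiovascular domain.

    Parameters
    ----------
    map_mmhg : float
        Mean arterial pressure, mmHg.
    dopamine, epinephrine, norepinephrine : float
        Infusion rates in ug/kg/min (0 when not running).
    dobutamine_any : bool
        Dobutamine at any dose scores at least 2.

    The highest applicable score wins: MAP >= 70 with no agents scores 0,
    hypotension alone scores 1, low-dose dopamine or any dobutamine scores
    2, mid-dose dopamine or low-dose epinephrine/norepinephrine scores 3,
    and high-dose agents score 4.
    """
    if not math.isfinite(map_mmhg) or map_mmhg <= 0:
        raise InvalidInputError(f"MAP must be finite and > 0, got {map_mmhg!r}")
    for name, rate in (
        ("dopamine", dopamine),
        ("epinephrine", epinephrine),
        ("norepinephrine", norepinephrine),
    ):
        _check_finite_nonneg(name, rate)

    score = 0
    if map_mmhg < 70:
        score = 1
    if (0 < dopamine <= 5) or dobutamine_any:
        score = max(score, 2)
    if dopamine > 5 or (0 < epinephrine <= 0.1) or (0 < norepinephrine <= 0.1):
        score = max(score, 3)
    if dopamine > 15 or epinephrine > 0.1 or norepinephrine > 0.1:
        score = max(score, 4)
    return score


def score_cns(gcs: int) -> int:
    """Score the central-nervous-system domain from the Glasgow Coma Scale."""
    if not isinstance(gcs, (int, float)) or not math.isfinite(gcs):
        raise InvalidInputError(f"GCS must be a finite number, got {gcs!r}")
    if gcs != int(gcs) or not 3 <= gcs <= 15:
        raise InvalidInputError(f"GCS must be an integer in [3, 15], got {gcs!r}")
    gcs = int(gcs)
    if gcs == 15:
        return 0
    if gcs >= 13:
        return 1
    if gcs >= 10:
        return 2
    if gcs >= 6:
        return 3
    return 4


def score_renal(creatinine: float, urine_24h: Optional[float] = None) -> int:
    """Score the renal domain from creatinine (mg/dL) and 24-h urine (mL).

    The score is the maximum of the creatinine-based score and, when a
    24-h urine total is available, the oliguria-based score (< 500 mL
    scores 3, < 200 mL scores 4).
    """
    _check_finite_nonneg("creatinine", creatinine)
    if creatinine < 1.2:
        score = 0
    elif creatinine < 2.0:
        score = 1
    elif creatinine < 3.5:
        score = 2
    elif creatinine < 5.0:
        score = 3
    else:
        score = 4
    if urine_24h is not None:
        _check_finite_nonneg("urine_24h", urine_24h)
        if urine_24h < 200:
            score = max(score, 4)
        elif urine_24h < 500:
            score = max(score, 3)
    return score


def total_sofa(components: list[ComponentScore] | dict[Component, ComponentScore]) -> int:
    """Sum the six component scores into the total SOFA score (0-24).

    Requires exactly one :class:`ComponentScore` per organ domain.
    """
    if isinstance(components, dict):
        scores = list(components.values())
    else:
        scores = list(components)
    seen = [c.component for c in scores]
    if sorted(seen, key=lambda c: c.value) != sorted(COMPONENTS, key=lambda c: c.value):
        raise InvalidInputError(
            f"need exactly one score per domain, got {[c.value for c in seen]}"
        )
    return sum(c.score for c in scores)
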
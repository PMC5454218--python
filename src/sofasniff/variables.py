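"""The observation variable vocabulary.

Every raw input the engine understands is one of these variables.  Each
has a fixed canonical unit; the CSV reader rejects a mismatched unit
string rather than attempting conversion.  Variables fall into staleness
classes that control how long an observation may be carried forward past
the evaluation window (labs persist longer than vitals, infusion rates
barely at all, on/off status flags persist for a day).
"""

from __future__ import annotations

from .errors import UnitError, UnknownVariableError

# variable -> (canonical unit, staleness class, is_boolean)
VARIABLE_REGISTRY: dict[str, tuple[str, str, bool]] = {
    "pao2": ("mmHg", "vitals", False),
    "fio2": ("fraction", "vitals", False),
    "pf_ratio": ("mmHg", "vitals", False),
    "platelets": ("10^3/uL", "labs", False),
    "bilirubin": ("mg/dL", "labs", False),
    "map": ("mmHg", "vitals", False),
    "dopamine_rate": ("ug/kg/min", "rates", False),
    "dobutamine_flag": ("bool", "rates", True),
    "epinephrine_rate": ("ug/kg/min", "rates", False),
    "norepinephrine_rate": ("ug/kg/min", "rates", False),
    "gcs": ("points", "vitals", False),
    "creatinine": ("mg/dL", "labs", False),
    "urine_output_increment": ("mL", "labs", False),
    "respiratory_support_flag": ("bool", "status", True),
}

# accepted case-insensitive spellings per canonical unit
_UNIT_ALIASES: dict[str, set[str]] = {
    "mmHg": {"mmhg"},
    "fraction": {"fraction", "frac"},
    "10^3/uL": {"10^3/ul", "10e3/ul", "x10^3/ul", "k/ul"},
    "mg/dL": {"mg/dl"},
    "ug/kg/min": {"ug/kg/min", "mcg/kg/min", "µg/kg/min"},
    "points": {"points", "point", ""},
    "bool": {"bool", "boolean", "flag", ""},
    "mL": {"ml"},
}

VARIABLES = frozenset(VARIABLE_REGISTRY)


def canonical_unit(variable: str) -> str:
    try:
        return VARIABLE_REGISTRY[variable][0]
    except KeyError:
        raise UnknownVariableError(f"unknown variable {variable!r}") from None


def staleness_class(variable: str) -> str:
    try:
        return VARIABLE_REGISTRY[variable][1]
    except KeyError:
        raise UnknownVariableError(f"unknown variable {variable!r}") from None


def is_boolean(variable: str) -> bool:
    try:
        return VARIABLE_REGISTRY[variable][2]
    except KeyError:
        raise UnknownVariableError(f"unknown variable {variable!r}") from None


def validate_unit(variable: str, unit: str) -> None:
    """Raise :class:`UnitError` unless ``unit`` matches the variable's unit."""
    canon = canonical_unit(variable)
    if unit == canon:
        return
    if unit.strip().lower() in _UNIT_ALIASES[canon]:
        return
    raise UnitError(
        f"variable {variable!r} expects unit {canon!r}, got {unit!r} (no conversion is attempted)"
    )
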
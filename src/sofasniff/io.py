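"""CSV and JSON interchange.

Observation streams travel as a flat CSV dialect with the header
``patient_id,timestamp,variable,value,unit``.  Timestamps must be
ISO-8601 *with* a UTC offset — naive timestamps are rejected, as are
unknown variable names and mismatched unit strings (no silent unit
conversion).  Writers emit deterministic output: fixed column order,
fixed float formatting, ``\\n`` line endings.
"""

from __future__ import annotations

import csv
import json
from datetime import datetime
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .detector import SepsisIndicator
from .errors import InvalidInputError
from .scoring import Component
from .timeline import Observation, PatientTimeline, SofaSeries
from .variables import is_boolean

OBSERVATION_COLUMNS = ["patient_id", "timestamp", "variable", "value", "unit"]
TIME_MOTION_COLUMNS = ["clinician_id", "hospital_day", "score_type", "seconds", "instrument"]
LIKERT_COLUMNS = ["respondent_id", "role", "item_id", "rating"]

_TRUE = {"true", "1", "t", "yes"}
_FALSE = {"false", "0", "f", "no"}


def _parse_timestamp(text: str, where: str) -> datetime:
    try:
        ts = datetime.fromisoformat(text)
    except ValueError as exc:
        raise InvalidInputError(f"{where}: bad timestamp {text!r}") from exc
    if ts.tzinfo is None or ts.tzinfo.utcoffset(ts) is None:
        raise InvalidInputError(
            f"{where}: timestamp {text!r} is naive; a UTC offset is required"
        )
    return ts


def _parse_value(variable: str, text: str, where: str):
    if is_boolean(variable):
        low = text.strip().lower()
        if low in _TRUE:
            return True
        if low in _FALSE:
            return False
        raise InvalidInputError(f"{where}: flag value must be boolean-like, got {text!r}")
    try:
        return float(text)
    except ValueError as exc:
        raise InvalidInputError(f"{where}: bad numeric value {text!r}") from exc


def read_observations(path: str | Path) -> dict[str, PatientTimeline]:
    """Read an observations CSV into per-patient timelines.

    Rows are validated strictly (known variable, matching unit,
    timezone-aware timestamp, sign/range constraints); any bad row raises
    a named error identifying the line.
    """
    path = Path(path)
    by_patient: dict[str, list[Observation]] = {}
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [c.strip() for c in reader.fieldnames] != OBSERVATION_COLUMNS:
            raise InvalidInputError(
                f"{path}: header must be exactly {','.join(OBSERVATION_COLUMNS)}"
            )
        for lineno, row in enumerate(reader, start=2):
            where = f"{path}:{lineno}"
            variable = row["variable"].strip()
            obs = Observation(
                patient_id=row["patient_id"].strip(),
                timestamp=_parse_timestamp(row["timestamp"].strip(), where),
                variable=variable,
                value=_parse_value(variable, row["value"], where),
                unit=row["unit"].strip(),
            )
            by_patient.setdefault(obs.patient_id, []).append(obs)
    return {pid: PatientTimeline(pid, obs) for pid, obs in sorted(by_patient.items())}


def _format_value(variable: str, value) -> str:
    if is_boolean(variable):
        return "true" if value else "false"
    return format(float(value), ".6g")


def write_observations(observations: Iterable[Observation], path: str | Path) -> None:
    """Write an observation stream as CSV (deterministic formatting)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(OBSERVATION_COLUMNS)
        for o in observations:
            w.writerow(
                [
                    o.patient_id,
                    o.timestamp.isoformat(),
                    o.variable,
                    _format_value(o.variable, o.value),
                    o.unit,
                ]
            )


def scores_header() -> list[str]:
    cols = ["patient_id", "eval_time", "window_start"]
    cols += [f"{c.value}_score" for c in Component]
    cols += [f"{c.value}_missing" for c in Component]
    cols += [f"{c.value}_carried" for c in Component]
    cols.append("total")
    return cols


def write_scores(series_list: Sequence[SofaSeries], path: str | Path) -> None:
    """Write SOFA series as CSV, one row per patient per grid instant."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(scores_header())
        for series in series_list:
            for s in series.scores:
                row = [series.patient_id, s.eval_time.isoformat(), s.window.start.isoformat()]
                row += [s.components[c].score for c in Component]
                row += [str(s.components[c].missing).lower() for c in Component]
                row += [str(s.components[c].carried_forward).lower() for c in Component]
                row.append(s.total)
                w.writerow(row)


def write_indicators(
    indicators_by_patient: Mapping[str, Sequence[SepsisIndicator]], path: str | Path
) -> None:
    """Write indicator states as CSV."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["patient_id", "eval_time", "baseline_total", "current_total", "delta", "triggered"])
        for pid in indicators_by_patient:
            for ind in indicators_by_patient[pid]:
                w.writerow(
                    [
                        pid,
                        ind.eval_time.isoformat(),
                        ind.baseline_total,
                        ind.current_total,
                        ind.delta,
                        str(ind.triggered).lower(),
                    ]
                )


def patient_report(
    series: SofaSeries,
    indicators: Sequence[SepsisIndicator],
    first_trigger_time: Optional[datetime],
) -> dict:
    """Per-patient JSON-ready report mirroring the score display contract:

    current/baseline/previous totals per grid time, per-component scores
    with missing/carried flags, and the source value and timestamp behind
    every non-missing component.
    """
    entries = []
    for s, ind in zip(series.scores, indicators):
        comps = {}
        for c in Component:
            cs = s.components[c]
            comps[c.value] = {
                "score": cs.score,
                "missing": cs.missing,
                "carried_forward": cs.carried_forward,
                "source_variable": cs.source_variable,
                "source_value": cs.source_value,
                "source_timestamp": (
                    cs.source_timestamp.isoformat() if cs.source_timestamp else None
                ),
            }
        entries.append(
            {
                "eval_time": s.eval_time.isoformat(),
                "window_start": s.window.start.isoformat(),
                "total": s.total,
                "delta": ind.delta,
                "triggered": ind.triggered,
                "components": comps,
            }
        )
    return {
        "patient_id": series.patient_id,
        "admission": series.admission.isoformat(),
        "baseline_total": indicators[0].baseline_total if indicators else None,
        "first_trigger_time": first_trigger_time.isoformat() if first_trigger_time else None,
        "scores": entries,
    }


def write_report(reports: Sequence[dict], path: str | Path) -> None:
    Path(path).write_text(json.dumps(reports, indent=2, sort_keys=False) + "\n")


def read_time_motion(path: str | Path) -> pd.DataFrame:
    """Read time-motion records; validates columns and positive durations."""
    df = pd.read_csv(path)
    if list(df.columns) != TIME_MOTION_COLUMNS:
        raise InvalidInputError(
            f"{path}: header must be exactly {','.join(TIME_MOTION_COLUMNS)}"
        )
    if (df["seconds"] <= 0).any():
        raise InvalidInputError(f"{path}: seconds must be > 0")
    if (df["hospital_day"] < 1).any():
        raise InvalidInputError(f"{path}: hospital_day must be >= 1")
    bad = set(df["score_type"]) - {"baseline", "current"}
    if bad:
        raise InvalidInputError(f"{path}: unknown score_type values {sorted(bad)}")
    return df


def read_likert(path: str | Path) -> pd.DataFrame:
    """Read Likert questionnaire responses; ratings must be integers 1-5."""
    df = pd.read_csv(path)
    if list(df.columns) != LIKERT_COLUMNS:
        raise InvalidInputError(f"{path}: header must be exactly {','.join(LIKERT_COLUMNS)}")
    if not df["rating"].isin([1, 2, 3, 4, 5]).all():
        raise InvalidInputError(f"{path}: ratings must be integers in [1, 5]")
    return df
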
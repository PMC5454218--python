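"""Time-motion workload analytics.

Summaries of observed manual score-calculation times, a Welch two-sample
comparison between baseline and current calculations, an ordinary
least-squares regression of calculation time on hospital day, and the
annual workload extrapolation: assuming one manual calculation per
patient day, the yearly time cost of a unit is

    total_hours = mean_seconds * patient_days / 3600

with the spread scaled the same way, and a per-bed figure obtained by
dividing by the bed count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError

__all__ = [
    "GroupSummary",
    "WelchResult",
    "RegressionResult",
    "WorkloadEstimate",
    "summarize_times",
    "compare_groups",
    "regress_time_on_day",
    "extrapolate_workload",
    "pooled_mean",
]


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean_seconds: float
    sd_seconds: float  # sample SD (n-1 denominator); 0 for n == 1


@dataclass(frozen=True)
class WelchResult:
    mean_difference: float
    statistic: float
    df: float
    p_value: float


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float


@dataclass(frozen=True)
class WorkloadEstimate:
    mean_seconds: float
    sd_seconds: float
    patient_days: int
    beds: int
    total_hours: float
    total_hours_sd: float
    per_bed_hours: float


def _as_array(values: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise InvalidInputError(f"{name} must be non-empty")
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise InvalidInputError(f"{name} must contain finite positive durations")
    return arr


def _summary(values: np.ndarray) -> GroupSummary:
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    return GroupSummary(int(values.size), float(np.mean(values)), sd)


def summarize_times(records: pd.DataFrame) -> dict[str, GroupSummary]:
    """Mean and sample SD of calculation seconds, overall and per score type.

    ``records`` needs ``seconds`` and ``score_type`` columns (the
    observations CSV dialect of :func:`sofasniff.io.read_time_motion`).
    """
    if len(records) == 0:
        raise InvalidInputError("no time-motion records")
    out = {"overall": _summary(_as_array(records["seconds"], "seconds"))}
    for score_type, grp in records.groupby("score_type", sort=True):
        out[str(score_type)] = _summary(_as_array(grp["seconds"], f"{score_type} seconds"))
    return out


def pooled_mean(summaries: Sequence[GroupSummary]) -> float:
    """Sample-size-weighted mean of group means."""
    n = sum(s.n for s in summaries)
    if n == 0:
        raise InvalidInputError("no observations to pool")
    return sum(s.n * s.mean_seconds for s in summaries) / n


def compare_groups(
    baseline_times: Sequence[float], current_times: Sequence[float]
) -> WelchResult:
    """Welch's unequal-variance t test between the two timing groups."""
    a = _as_array(baseline_times, "baseline_times")
    b = _as_array(current_times, "current_times")
    if a.size < 2 or b.size < 2:
        raise InvalidInputError("each group needs at least 2 records")
    res = stats.ttest_ind(a, b, equal_var=False)
    return WelchResult(
        mean_difference=float(np.mean(a) - np.mean(b)),
        statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
    )


def regress_time_on_day(records: pd.DataFrame) -> RegressionResult:
    """OLS of calculation seconds on hospital day (one score type at a time)."""
    if len(records) < 3:
        raise InvalidInputError("need at least 3 records to regress")
    x = np.asarray(records["hospital_day"], dtype=float)
    y = _as_array(records["seconds"], "seconds")
    if np.unique(x).size < 2:
        raise InvalidInputError("hospital_day must take at least 2 distinct values")
    if np.ptp(y) == 0:  # constant response: flat fit, no variance explained
        return RegressionResult(slope=0.0, intercept=float(y[0]), r_squared=0.0, p_value=1.0)
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
    )


def extrapolate_workload(
    mean_seconds: float, sd_seconds: float, patient_days: int, beds: int
) -> WorkloadEstimate:
    """Annual workload of one manual score calculation per patient day.

    Hours scale linearly from seconds (factor exactly 3600); the SD is
    propagated by the same scaling.
    """
    for name, v in (
        ("mean_seconds", mean_seconds),
        ("patient_days", patient_days),
        ("beds", beds),
    ):
        if not np.isfinite(v) or v <= 0:
            raise InvalidInputError(f"{name} must be finite and > 0")
    if not np.isfinite(sd_seconds) or sd_seconds < 0:
        raise InvalidInputError("sd_seconds must be finite and >= 0")
    total_hours = mean_seconds * patient_days / 3600.0
    total_hours_sd = sd_seconds * patient_days / 3600.0
    return WorkloadEstimate(
        mean_seconds=float(mean_seconds),
        sd_seconds=float(sd_seconds),
        patient_days=int(patient_days),
        beds=int(beds),
        total_hours=total_hours,
        total_hours_sd=total_hours_sd,
        per_bed_hours=total_hours / beds,
    )


def workload_report(
    records: Optional[pd.DataFrame], patient_days: int, beds: int
) -> dict:
    """Full analysis bundle for one unit as a JSON-ready mapping."""
    out: dict = {}
    if records is not None and len(records):
        summaries = summarize_times(records)
        out["summaries"] = {
            k: {"n": s.n, "mean_seconds": s.mean_seconds, "sd_seconds": s.sd_seconds}
            for k, s in summaries.items()
        }
        base = records.loc[records["score_type"] == "baseline", "seconds"]
        curr = records.loc[records["score_type"] == "current", "seconds"]
        if len(base) >= 2 and len(curr) >= 2:
            w = compare_groups(base, curr)
            out["baseline_vs_current"] = {
                "mean_difference_seconds": w.mean_difference,
                "t_statistic": w.statistic,
                "df": w.df,
                "p_value": w.p_value,
            }
        by_day = records[records["score_type"] == "baseline"]
        if len(by_day) >= 3 and by_day["hospital_day"].nunique() >= 2:
            r = regress_time_on_day(by_day)
            out["baseline_time_on_day"] = {
                "slope": r.slope,
                "intercept": r.intercept,
                "r_squared": r.r_squared,
                "p_value": r.p_value,
            }
        overall = summaries["overall"]
        est = extrapolate_workload(overall.mean_seconds, overall.sd_seconds, patient_days, beds)
    else:
        raise InvalidInputError("no time-motion records")
    out["extrapolation"] = {
        "mean_seconds": est.mean_seconds,
        "sd_seconds": est.sd_seconds,
        "patient_days": est.patient_days,
        "beds": est.beds,
        "total_hours": est.total_hours,
        "total_hours_rounded": round(est.total_hours),
        "total_hours_sd": est.total_hours_sd,
        "per_bed_hours": est.per_bed_hours,
    }
    return out
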
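"""Independent brute-force oracle for the rolling-window scorer.

Re-derives the SOFA series by re-scanning the raw observation list for
every grid point, with its own hand-coded cut-point tables and its own
window/carry/pairing logic, so tests can compare the engine against an
implementation that shares no code with it.
"""

from __future__ import annotations

from datetime import datetime, timedelta

from sofasniff.config import EngineConfig
from sofasniff.timeline import Observation

COMPONENTS = ["respiratory", "coagulation", "liver", "cardiovascular", "cns", "renal"]

CARDIO_DRIVERS = [
    "map",
    "dopamine_rate",
    "dobutamine_flag",
    "epinephrine_rate",
    "norepinephrine_rate",
]


def pf_score(ratio: float, support: bool) -> int:
    for cut, sc in ((100, 4), (200, 3), (300, 2), (400, 1)):
        if ratio < cut:
            return sc if support or sc <= 2 else 2
    return 0


def plt_score(v: float) -> int:
    for cut, sc in ((20, 4), (50, 3), (100, 2), (150, 1)):
        if v < cut:
            return sc
    return 0


def bili_score(v: float) -> int:
    for cut, sc in ((12.0, 4), (6.0, 3), (2.0, 2), (1.2, 1)):
        if v >= cut:
            return sc
    return 0


def cardio_score(mp, dop, dob, epi, nor) -> int:
    candidates = [0]
    if mp < 70:
        candidates.append(1)
    if 0 < dop <= 5 or dob:
        candidates.append(2)
    if dop > 5 or 0 < epi <= 0.1 or 0 < nor <= 0.1:
        candidates.append(3)
    if dop > 15 or epi > 0.1 or nor > 0.1:
        candidates.append(4)
    return max(candidates)


def gcs_score(v: int) -> int:
    table = {15: 0, 14: 1, 13: 1, 12: 2, 11: 2, 10: 2}
    if v in table:
        return table[v]
    return 3 if v >= 6 else 4


def creat_score(v: float) -> int:
    for cut, sc in ((5.0, 4), (3.5, 3), (2.0, 2), (1.2, 1)):
        if v >= cut:
            return sc
    return 0


def urine_score(v: float, window_hours: float) -> int:
    f = window_hours / 24.0
    if v < 200 * f:
        return 4
    if v < 500 * f:
        return 3
    return 0


def naive_sofa_at(observations: list[Observation], t: datetime, cfg: EngineConfig):
    """One grid point, recomputed from the flat observation list.

    Returns ``{component: (score, missing, carried, source_ts, source_var,
    source_val)}`` plus the total, in the same shape the engine exposes.
    """
    start = t - timedelta(hours=cfg.window_hours)

    def var_obs(var):
        return sorted(
            (o for o in observations if o.variable == var), key=lambda o: o.timestamp
        )

    def carry(var):
        return timedelta(hours=cfg.carry_hours(var))

    def candidates(var):
        objs = var_obs(var)
        in_win = [o for o in objs if start < o.timestamp <= t]
        if in_win:
            return [(o.timestamp, o.value, False) for o in in_win]
        older = [o for o in objs if o.timestamp <= start]
        if older:
            last = older[-1]
            if t - last.timestamp <= carry(var):
                return [(last.timestamp, last.value, True)]
        return []

    def latest_at(var, instant):
        objs = [o for o in var_obs(var) if o.timestamp <= instant]
        if objs and instant - objs[-1].timestamp <= carry(var):
            return objs[-1].value
        return None

    def closest_fio2(instant):
        tol = timedelta(minutes=cfg.pairing_tolerance_minutes)
        objs = [o for o in var_obs("fio2") if o.timestamp <= t]
        best, best_dt = None, None
        for o in objs:
            dt = abs(o.timestamp - instant)
            if dt <= tol and (best_dt is None or dt < best_dt):
                best, best_dt = o.value, dt
        return best

    results = {}

    # respiratory
    snaps = []
    for ts, v, car in candidates("pf_ratio"):
        snaps.append((ts, v, car))
    for ts, v, car in candidates("pao2"):
        fio2 = closest_fio2(ts)
        snaps.append((ts, v / (fio2 if fio2 is not None else cfg.room_air_fio2), car))
    if snaps:
        scored = []
        for ts, ratio, car in snaps:
            support = latest_at("respiratory_support_flag", ts)
            scored.append((pf_score(ratio, bool(support)), ts, ratio, car))
        best = max(s for s, *_ in scored)
        hit = sorted((x for x in scored if x[0] == best), key=lambda x: x[1])[0]
        results["respiratory"] = (best, False, hit[3], hit[1], "pf_ratio", hit[2])
    else:
        results["respiratory"] = (cfg.missing_score, True, False, None, None, None)

    # single-driver domains
    for comp, var, fn in (
        ("coagulation", "platelets", plt_score),
        ("liver", "bilirubin", bili_score),
        ("cns", "gcs", lambda v: gcs_score(int(v))),
    ):
        cands = candidates(var)
        if cands:
            scored = [(fn(v), ts, v, car) for ts, v, car in cands]
            best = max(s for s, *_ in scored)
            hit = sorted((x for x in scored if x[0] == best), key=lambda x: x[1])[0]
            results[comp] = (best, False, hit[3], hit[1], var, hit[2])
        else:
            results[comp] = (cfg.missing_score, True, False, None, None, None)

    # cardiovascular
    snaps = []
    for var in CARDIO_DRIVERS:
        for ts, v, car in candidates(var):
            snaps.append((ts, v, car, var))
    if snaps:
        scored = []
        for ts, v, car, var in snaps:
            vals = {}
            for other in CARDIO_DRIVERS:
                vals[other] = v if other == var else latest_at(other, ts)
            sc = cardio_score(
                vals["map"] if vals["map"] is not None else 75.0,
                vals["dopamine_rate"] or 0.0,
                bool(vals["dobutamine_flag"]),
                vals["epinephrine_rate"] or 0.0,
                vals["norepinephrine_rate"] or 0.0,
            )
            scored.append((sc, ts, v, car, var))
        best = max(s for s, *_ in scored)
        hit = sorted(
            (x for x in scored if x[0] == best),
            key=lambda x: (x[1], CARDIO_DRIVERS.index(x[4])),
        )[0]
        results["cardiovascular"] = (best, False, hit[3], hit[1], hit[4], hit[2])
    else:
        results["cardiovascular"] = (cfg.missing_score, True, False, None, None, None)

    # renal
    scored = [
        (creat_score(v), ts, v, car, "creatinine") for ts, v, car in candidates("creatinine")
    ]
    incr = [o for o in var_obs("urine_output_increment") if start < o.timestamp <= t]
    if len(incr) >= 2:
        span = (incr[-1].timestamp - incr[0].timestamp) / timedelta(hours=cfg.window_hours)
        if span >= cfg.urine_coverage_fraction:
            total = float(sum(o.value for o in incr))
            scored.append(
                (urine_score(total, cfg.window_hours), t, total, False, "urine_output_24h")
            )
    if scored:
        best = max(s for s, *_ in scored)
        hit = sorted((x for x in scored if x[0] == best), key=lambda x: x[1])[0]
        results["renal"] = (best, False, hit[3], hit[1], hit[4], hit[2])
    else:
        results["renal"] = (cfg.missing_score, True, False, None, None, None)

    total = sum(results[c][0] for c in COMPONENTS)
    return results, total


def engine_score_as_tuples(sofa_score):
    """Flatten an engine SofaScore into the oracle's comparison shape."""
    out = {}
    for comp, cs in sofa_score.components.items():
        out[comp.value] = (
            cs.score,
            cs.missing,
            cs.carried_forward,
            cs.source_timestamp,
            cs.source_variable,
            cs.source_value,
        )
    return out, sofa_score.total
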
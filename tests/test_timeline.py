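"""Timeline engine: grid, window semantics, worst-value aggregation, provenance."""

from __future__ import annotations

from datetime import datetime, timedelta, timezone

import pytest

from conftest import T0, obs, ts
from sofasniff.config import EngineConfig
from sofasniff.errors import InvalidInputError, UnknownVariableError
from sofasniff.scoring import Component
from sofasniff.timeline import (
    EvaluationWindow,
    Observation,
    PatientTimeline,
    compute_series,
    compute_sofa_at,
    effective_observations,
    recalculation_grid,
)


# -- recalculation grid ------------------------------------------------------


def test_grid_aligns_to_quarter_hours():
    start = T0 + timedelta(minutes=7)
    end = T0 + timedelta(hours=1)
    grid = recalculation_grid(start, end)
    assert grid == [T0 + timedelta(minutes=m) for m in (15, 30, 45, 60)]


def test_grid_full_day_has_97_points():
    grid = recalculation_grid(T0, T0 + timedelta(hours=24))
    assert len(grid) == 97
    assert grid[0] == T0 and grid[-1] == T0 + timedelta(hours=24)


def test_grid_short_span_keeps_aligned_admission():
    assert recalculation_grid(T0, T0 + timedelta(minutes=10)) == [T0]


def test_grid_rejects_bad_ranges():
    with pytest.raises(InvalidInputError):
        recalculation_grid(T0, T0)
    with pytest.raises(InvalidInputError):
        recalculation_grid(T0, T0 - timedelta(hours=1))
    with pytest.raises(InvalidInputError):
        recalculation_grid(T0, T0 + timedelta(hours=1), timedelta(0))


def test_grid_rejects_naive_timestamps():
    with pytest.raises(InvalidInputError):
        recalculation_grid(datetime(2024, 3, 1), T0 + timedelta(hours=1))


# -- observations and windows ------------------------------------------------


def test_observation_rejects_naive_timestamp_and_unknown_variable():
    with pytest.raises(InvalidInputError):
        Observation("P1", datetime(2024, 3, 1), "map", 80.0)
    with pytest.raises(UnknownVariableError):
        obs_bad = Observation("P1", ts(0), "heart_rate", 80.0)


def test_observation_rejects_flag_without_boolean():
    with pytest.raises(InvalidInputError):
        Observation("P1", ts(0), "respiratory_support_flag", 1.0)


def test_window_is_half_open(timeline_factory, config):
    """An observation exactly at window.start is excluded; at window.end included."""
    t = ts(24)
    at_start = timeline_factory([obs("platelets", 0, 30.0)])
    at_end = timeline_factory([obs("platelets", 24, 30.0)])
    s_start = compute_sofa_at(at_start, t, config)
    s_end = compute_sofa_at(at_end, t, config)
    # the start observation is out of window but within lab carry age
    cs = s_start.components[Component.COAGULATION]
    assert cs.carried_forward and cs.score == 3
    cs = s_end.components[Component.COAGULATION]
    assert not cs.carried_forward and not cs.missing and cs.score == 3


# -- effective observations (carry-forward) ----------------------------------


def test_effective_in_window(timeline_factory):
    tl = timeline_factory([obs("platelets", 23, 80.0)])
    window = EvaluationWindow(ts(0), ts(24))
    cands = effective_observations(tl, "platelets", window, timedelta(hours=48))
    assert len(cands) == 1 and not cands[0].carried


def test_effective_carried_within_age(timeline_factory):
    tl = timeline_factory([obs("platelets", -6, 80.0)])
    window = EvaluationWindow(ts(0), ts(24))
    cands = effective_observations(tl, "platelets", window, timedelta(hours=48))
    assert len(cands) == 1 and cands[0].carried
    assert cands[0].timestamp == ts(-6)


def test_effective_absent_beyond_age(timeline_factory):
    tl = timeline_factory([obs("platelets", -6, 80.0)])
    window = EvaluationWindow(ts(0), ts(24))
    assert effective_observations(tl, "platelets", window, timedelta(hours=24)) == []


def test_in_window_observations_suppress_carry(timeline_factory):
    tl = timeline_factory([obs("platelets", -6, 10.0), obs("platelets", 12, 80.0)])
    window = EvaluationWindow(ts(0), ts(24))
    cands = effective_observations(tl, "platelets", window, timedelta(hours=48))
    assert [c.carried for c in cands] == [False]
    assert cands[0].value == 80.0


# -- compute_sofa_at ---------------------------------------------------------


def worst_case_timeline(timeline_factory):
    return timeline_factory(
        [
            obs("pf_ratio", 20, 90.0),
            obs("respiratory_support_flag", 19, True),
            obs("platelets", 18, 45.0),
            obs("bilirubin", 17, 3.0),
            obs("map", 20.5, 60.0),
            obs("norepinephrine_rate", 20.4, 0.2),
            obs("gcs", 21, 12),
            obs("creatinine", 16, 3.0),
        ]
    )


def test_worst_values_total_17(timeline_factory, config):
    s = compute_sofa_at(worst_case_timeline(timeline_factory), ts(24), config)
    got = {c.value: s.components[c].score for c in Component}
    assert got == {
        "respiratory": 4,
        "coagulation": 3,
        "liver": 2,
        "cardiovascular": 4,
        "cns": 2,
        "renal": 2,
    }
    assert s.total == 17


def test_empty_timeline_all_missing(timeline_factory, config):
    s = compute_sofa_at(timeline_factory([]), ts(24), config)
    assert s.total == 0
    assert all(cs.missing for cs in s.components.values())
    assert all(cs.source_timestamp is None for cs in s.components.values())


def test_single_component_timeline(timeline_factory, config):
    s = compute_sofa_at(timeline_factory([obs("platelets", 12, 19.0)]), ts(24), config)
    assert s.components[Component.COAGULATION].score == 4
    missing = [c for c in Component if s.components[c].missing]
    assert len(missing) == 5 and Component.COAGULATION not in missing
    assert s.total == 4


def test_worst_value_wins_within_window(timeline_factory, config):
    tl = timeline_factory([obs("platelets", 2, 160.0), obs("platelets", 10, 40.0), obs("platelets", 20, 130.0)])
    cs = compute_sofa_at(tl, ts(24), config).components[Component.COAGULATION]
    assert cs.score == 3
    assert cs.source_timestamp == ts(10) and cs.source_value == 40.0


def test_earliest_achieving_snapshot_is_source(timeline_factory, config):
    tl = timeline_factory([obs("platelets", 5, 45.0), obs("platelets", 15, 30.0)])
    cs = compute_sofa_at(tl, ts(24), config).components[Component.COAGULATION]
    assert cs.score == 3 and cs.source_timestamp == ts(5)


def test_pao2_fio2_pairing(timeline_factory, config):
    """PaO2 pairs with the temporally closest FiO2 within the tolerance."""
    tl = timeline_factory(
        [obs("pao2", 10, 80.0), obs("fio2", 10.5, 0.8), obs("fio2", 8.0, 0.4)]
    )
    cs = compute_sofa_at(tl, ts(24), config).components[Component.RESPIRATORY]
    assert cs.source_value == pytest.approx(100.0)  # 80 / 0.8
    assert cs.score == 2  # ratio 100 without support caps at 2


def test_pao2_without_fio2_assumes_room_air(timeline_factory, config):
    tl = timeline_factory([obs("pao2", 10, 84.0)])
    cs = compute_sofa_at(tl, ts(24), config).components[Component.RESPIRATORY]
    assert cs.source_value == pytest.approx(84.0 / 0.21)
    assert cs.score == 0


def test_respiratory_support_resolved_at_snapshot(timeline_factory, config):
    """Support status is taken from the latest flag at or before the gas draw."""
    tl = timeline_factory(
        [
            obs("respiratory_support_flag", 0, False),
            obs("pf_ratio", 5, 90.0),
            obs("respiratory_support_flag", 10, True),
            obs("pf_ratio", 12, 90.0),
        ]
    )
    cs = compute_sofa_at(tl, ts(24), config).components[Component.RESPIRATORY]
    assert cs.score == 4 and cs.source_timestamp == ts(12)


def test_cardiovascular_pairs_rate_with_recent_map(timeline_factory, config):
    tl = timeline_factory([obs("map", 20.0, 60.0), obs("norepinephrine_rate", 20.5, 0.05)])
    cs = compute_sofa_at(tl, ts(24), config).components[Component.CARDIOVASCULAR]
    assert cs.score == 3 and cs.source_variable == "norepinephrine_rate"


def test_stale_rate_not_carried_beyond_age(timeline_factory, config):
    """Infusion rates go stale after one hour; MAP alone then scores."""
    tl = timeline_factory([obs("norepinephrine_rate", 2, 0.2), obs("map", 26, 60.0)])
    s = compute_sofa_at(tl, ts(28), config)
    cs = s.components[Component.CARDIOVASCULAR]
    assert cs.score == 1 and cs.source_variable == "map"


def test_urine_total_scores_oliguria(timeline_factory, config):
    increments = [obs("urine_output_increment", h, 8.0) for h in range(1, 25)]
    cs = compute_sofa_at(timeline_factory(increments), ts(24), config).components[Component.RENAL]
    assert cs.score == 4  # 192 mL / 24 h
    assert cs.source_variable == "urine_output_24h" and cs.source_value == 192.0


def test_sparse_urine_is_ignored(timeline_factory, config):
    """Increments spanning less than half the window don't count as a total."""
    tl = timeline_factory(
        [obs("urine_output_increment", 22, 10.0), obs("urine_output_increment", 23, 10.0)]
    )
    cs = compute_sofa_at(tl, ts(24), config).components[Component.RENAL]
    assert cs.missing


def test_adding_observation_never_decreases_score(timeline_factory, config):
    """Worst-value aggregation is monotone under adding observations."""
    base = [obs("platelets", 5, 120.0), obs("bilirubin", 6, 1.0)]
    extra = obs("platelets", 10, 30.0)
    s0 = compute_sofa_at(timeline_factory(base), ts(24), config)
    s1 = compute_sofa_at(timeline_factory(base + [extra]), ts(24), config)
    for c in Component:
        assert s1.components[c].score >= s0.components[c].score


# -- compute_series ----------------------------------------------------------


def test_constant_observations_constant_series(timeline_factory, config):
    observations = [obs("platelets", h, 80.0) for h in range(0, 49)]
    series = compute_series(timeline_factory(observations), config)
    assert len(set(series.totals())) == 1
    assert series.totals()[0] == 2


def test_transient_pressor_decays_out_of_reach(timeline_factory, config):
    """A single norepinephrine dose drives the score while in window or carry
    reach of the evaluation instant, then the score drops."""
    tl = timeline_factory(
        [obs("map", 0, 80.0), obs("norepinephrine_rate", 10, 0.2), obs("map", 40, 80.0)]
    )
    series = compute_series(tl, config)
    by_time = {
        s.eval_time: s.components[Component.CARDIOVASCULAR].score for s in series.scores
    }
    assert by_time[ts(10)] == 4
    assert by_time[ts(33.75)] == 4  # hour 10 still inside the half-open window
    assert by_time[ts(34)] == 0  # window excludes its start; 1-h rate carry expired
    assert by_time[ts(40)] == 0  # normal MAP back in view


def test_series_provenance_within_reach(timeline_factory, config):
    tl = timeline_factory([obs("platelets", 1, 40.0), obs("map", 30, 80.0)])
    series = compute_series(tl, config)
    for s in series.scores:
        for cs in s.components.values():
            if cs.source_timestamp is not None:
                assert cs.source_timestamp <= s.eval_time
                if not cs.carried_forward:
                    assert s.window.start < cs.source_timestamp


def test_empty_timeline_series_raises(timeline_factory, config):
    with pytest.raises(InvalidInputError):
        compute_series(timeline_factory([]), config)


def test_carry_component_policy_repeats_previous_score(timeline_factory):
    cfg = EngineConfig(missing_policy="carry_component", carry_overrides_hours={"platelets": 1.0})
    tl = timeline_factory([obs("platelets", 0.0, 30.0), obs("map", 30, 80.0)])
    series = compute_series(tl, cfg)
    coag = [s.components[Component.COAGULATION] for s in series.scores]
    # once the observation leaves window and carry reach, the previous
    # component score is repeated and flagged missing + carried
    late = coag[-1]
    assert late.score == 3 and late.missing and late.carried_forward


def test_zero_policy_missing_scores_zero(timeline_factory, config):
    cfg = config.with_updates(carry_overrides_hours={"platelets": 1.0})
    tl = timeline_factory([obs("platelets", 0.0, 30.0), obs("map", 30, 80.0)])
    series = compute_series(tl, cfg)
    late = series.scores[-1].components[Component.COAGULATION]
    assert late.score == 0 and late.missing
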
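# Methods

## Scoring model

The six SOFA component scores follow the original sequential organ
failure assessment definition. Cut-points are implemented with exact
inequality directions (a platelet count of exactly 20 ×10³/µL scores 3,
not 4; a P/F ratio of exactly 400 scores 0) and are covered by boundary
tests at each cut ± ε. Two readings of the table required a decision:

* **Respiratory support qualifier.** Scores 3 and 4 carry the table's
  "with respiratory support" qualifier; without support the respiratory
  score saturates at 2 regardless of how low the ratio is.
* **Dobutamine** is a presence flag ("any dose"), not a rate threshold.
* **Cardiovascular** takes the highest applicable criterion (MAP-based
  and agent-based); **renal** is the maximum of the creatinine-based and
  oliguria-based scores.

## Rolling recalculation

A patient's score series is recalculated on a clock-aligned grid (every
15 minutes by default, so instants land on :00/:15/:30/:45 UTC; the grid
anchors to the clock rather than to admission because that is how a
unit-level dashboard refreshes). Each evaluation uses the half-open
trailing window `(t − 24 h, t]`: an observation exactly at the window
start belongs to the previous frame, one exactly at `t` is included.

"Most abnormal" is defined as the **maximum component score over
candidate snapshots**, not the worst raw value re-scored — the two
differ for multi-input components where raw inputs are not individually
monotone. Candidate snapshots are the in-window observations of a
component's driver variables; each snapshot is completed with the
*effective* values of its co-inputs at that instant (the latest co-input
observation at or before the snapshot, no older than its carry age).
Among snapshots achieving the maximal score, the earliest is recorded as
the source, ties across variables resolving in a fixed driver order.

* **Respiratory**: explicit P/F-ratio observations, plus ratios formed
  from each PaO2 and the temporally closest FiO2 within a pairing
  tolerance (default 60 min, ties to the earlier observation, future
  observations relative to the evaluation instant never used). PaO2
  without any eligible FiO2 assumes room air (FiO2 0.21). Ventilation
  status is resolved per snapshot from the latest support flag.
* **Cardiovascular**: MAP, three infusion rates and the dobutamine flag
  are all drivers; an unresolvable MAP defaults to normotension
  (agent criteria dominate whenever agents are running) and unresolved
  rates default to zero.
* **Renal**: creatinine candidates plus the windowed urine total — the
  sum of in-window urine increments, attributed to their timestamps. The
  total is used only when increments span at least a configured fraction
  of the window (default 0.5, measured first-to-last increment; a single
  increment never qualifies); oliguria thresholds (500/200 mL per 24 h)
  scale linearly with a non-default window length.

### Carry-forward and missing data

When a variable has no in-window observation, the most recent older
observation is carried forward if its age relative to the evaluation
instant is within the variable's staleness class: labs 48 h, vitals and
blood gases 4 h, infusion rates 1 h, on/off status flags 24 h (all
configurable per variable). These ages express clinically distinct
staleness tolerances: a platelet count is informative for days, an
infusion rate for minutes. Carried values are flagged `carried_forward`;
note that with the default 24-hour window, a rate's 1-hour carry age can
never exceed the window's own reach, so rates effectively disappear when
they leave the window.

A component with no usable data is flagged `missing` and, under the
default `zero` policy, scores 0 — absence of evidence never inflates the
total. The alternative `carry_component` policy repeats the previous
grid point's component score (still flagged missing) for displays that
prefer persistence over conservatism.

## Baseline and ΔSOFA

The indicator compares totals, not per-component deltas. Baseline
policies:

* `first_window` (default): the score at the first grid instant whose
  window has fully elapsed since admission — an admission-era reference;
  stays shorter than one window fall back to the last grid point;
* `assume_zero`: no known prior organ dysfunction;
* `fixed`: caller-provided.

The indicator is instantaneous by default (it reflects the current
delta, mirroring a state display rather than a sticky alarm); a latching
mode keeps it on once triggered. `first_trigger` reports the earliest
triggered grid instant.

## Synthetic EHR generator

Charting cadences emulate routine ICU documentation: labs every 24 ± 2 h,
vitals (MAP, GCS) hourly ± 10 min, blood gases every 6 ± 0.5 h, urine
increments hourly. Values are clipped Gaussians around in-band
representatives, with clip bounds strictly inside the scoring cut-points
so charting noise never changes a score. An injected failure event
(component, onset, target severity 0–4, ramp) densifies sampling of the
affected variable (every 2 h) and moves it into the target band: during
the ramp the variable deteriorates gradually but stays at severity ≤ 1,
and from ramp completion onward it sits exactly in the target band, so a
downstream ΔSOFA crossing is attributable to ramp completion. Severity
≥ 3 respiratory failure emits an FiO2 of 0.6 and a ventilation flag with
each gas (and refuses the spec if flag emission is disabled, since those
scores are unreachable without support); cardiovascular severity ≥ 2
starts a vasoactive infusion charted every 45 minutes from ramp
completion.

Per-patient cohort seeds are `splitmix64(base_seed + index + 1) mod 2³¹`,
so streams are stable across runs and machines.

What the generator does **not** emulate: pharmacokinetics, correlated
multi-organ dynamics, measurement error beyond truncated noise,
charting backlogs or documentation errors. Passing tests therefore show
that the engine implements its window/carry/worst-value semantics
correctly on plausible streams — not that it is validated against real
EMR data.

## Study analytics

* Timing summaries use the arithmetic mean and sample SD (n−1).
* The baseline-vs-current comparison uses Welch's unequal-variance t
  test (no equal-variance assumption is defensible given the observed
  SDs of 8.3 vs 36.0 s).
* Time-on-day uses ordinary least squares; a constant response is
  reported as slope 0 with R² = 0.
* The annual extrapolation reads "one calculation per patient day":
  `total_hours = mean_seconds × patient_days / 3600`, SD propagated by
  the same linear scaling, per-bed figure divided by the bed count.
  With a mean of 61.6 s over 6770 patient days this gives 115.8 h
  (≈ 116) and 4.83 h per bed over 24 beds; scaling the rounded SD of
  33 s gives ≈ 62 h.
* Likert ratings map 4–5 → favorable, 3 → neutral, 1–2 → unfavorable;
  the unit of analysis is the item-response. The default item→domain map
  is the standard 19-item CSUQ grouping (1–8 system usability, 9–15
  information quality, 16–18 interface quality, 19 overall-only); a
  custom map or an explicit `domain` column overrides it.

## Numerical and interface choices

* Timestamps must be timezone-aware everywhere; the CSV reader rejects
  naive timestamps, unknown variables, and mismatched unit strings (no
  silent conversion — accuracy over convenience).
* Grid arithmetic is exact (microsecond-resolution integer arithmetic
  from the Unix epoch), so grids never drift.
* Writers emit deterministic bytes: fixed column order, `%.6g` floats,
  `\n` line endings. Reruns with the same inputs are byte-identical.
* Exit codes: 0 success, 2 unreadable/malformed input, 3 invalid
  configuration.

## Problem sizes

The test suite checks engine/oracle equivalence on 105 random synthetic
timelines of 26–30 h (≈ 100–200 observations each, every grid point,
every component, flags and sources compared exactly) plus a non-default
configuration batch; the acceptance script re-runs 40 such timelines and
a 20-patient engineered cohort. These sizes exercise every code path —
window entry/exit, carry expiry, pairing, ramps in all six domains —
while keeping a full run in the tens of seconds.

## Known limitations

* Sepsis-3 proper also requires suspected infection; this package
  implements only the organ-dysfunction (ΔSOFA) arm.
* The worst-value snapshot semantics for multi-input components is one
  defensible operationalization; clinical deployments differ in how they
  pair co-inputs and bound carry-forward, and all such knobs are exposed
  in `EngineConfig` rather than hidden.
* Urine coverage is measured first-to-last increment, which slightly
  undercounts the covered period for sparse charting.
* No HL7/FHIR connectivity or streaming ingestion; input is batch CSV.
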
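# sofasniff

Automated rolling-window SOFA scoring and delta-SOFA sepsis screening for
ICU observation streams.

## The problem

The SOFA score (sequential organ failure assessment) sums six organ-domain
subscores — respiratory (PaO2/FiO2), coagulation (platelets), liver
(bilirubin), cardiovascular (MAP and vasopressors), CNS (Glasgow Coma
Scale) and renal (creatinine / urine output) — each 0–4, total 0–24.
Under the Sepsis-3 convention, an acute rise of the total by **ΔSOFA ≥ 2
over baseline** indicates sepsis-related organ dysfunction, so the score
must be recalculated continually: each recalculation takes the *most
abnormal* values of the trailing 24 hours, and the calculation frame
shifts forward every 15 minutes. Computing this by hand costs clinicians
roughly a minute per calculation; this package automates the whole
pipeline and keeps the provenance clinicians asked for — per-component
source values, missing-data flags, and carried-forward flags.

`sofasniff` provides:

* **scoring** — pure functions for the six SOFA component scores and
  their total;
* **timeline engine** — worst-value aggregation over a half-open
  `(t − 24 h, t]` window on a clock-aligned 15-minute grid, with
  per-variable carry-forward ages (labs 48 h, vitals 4 h, infusion rates
  1 h, status flags 24 h), PaO2/FiO2 pairing, and windowed urine totals;
* **sepsis detector** — baseline tracking (first full window, assumed
  zero, or fixed) and ΔSOFA ≥ 2 indicator states per grid instant;
* **synthetic EHR generator** — reproducible observation streams with
  realistic charting cadence and injectable organ-failure trajectories;
* **workload analytics** — time-motion summaries, Welch comparison,
  OLS of calculation time on hospital day, and the annual workload
  extrapolation `total_hours = mean_seconds × patient_days / 3600`;
* **usability analytics** — CSUQ Likert categorization (favorable 4–5 /
  neutral 3 / unfavorable 1–2) and per-domain favorability proportions.

## Worked example

Generate a 5-patient cohort in which one patient develops an engineered
organ failure after hour 30, then screen it:

```sh
$ sofasniff simulate --n 5 --seed 7 --failure-fraction 0.2 --stay-hours 48 \
      --out observations.csv
wrote 809 observations for 5 patients (1 with engineered organ failure) to observations.csv

$ sofasniff sniff --observations observations.csv --scores-out scores.csv \
      --indicators-out indicators.csv --report-out report.json
1/5 patients met the delta-SOFA criterion
```

`report.json` holds one entry per patient; the affected patient reads
`"baseline_total": 0` and `"first_trigger_time": "2024-03-02T18:00:00+00:00"`
— exactly onset (hour 30) + ramp (4 h) after the 2024-03-01 08:00
admission, because the injected trajectory crosses the ΔSOFA ≥ 2
threshold when its ramp completes. `scores.csv` has one row per patient
per 15-minute grid instant with the six component scores and their
missing/carried flags, e.g.

```
patient_id,eval_time,window_start,respiratory_score,...,total
P0001,2024-03-01T08:00:00+00:00,2024-02-29T08:00:00+00:00,0,...,0
```

The workload analysis on a time-motion CSV (here with subgroup means of
39.9 s and 83.4 s over 35 observations each):

```sh
$ sofasniff workload --records time_motion.csv --patient-days 6770 --beds 24
mean 61.6 s/calculation x 6770 patient days = 115.9 h/year (~116 h), 4.83 h per bed over 24 beds
```

i.e. one extra manual calculation per patient day in a 24-bed unit costs
about 116 clinician-hours a year — almost 5 hours per bed.

## Library use

```python
from sofasniff import (EngineConfig, PatientTimeline, compute_series,
                       baseline_score, indicator_series, first_trigger)
from sofasniff.io import read_observations

cfg = EngineConfig()                    # 24 h window, 15 min grid, delta >= 2
timelines = read_observations("observations.csv")
series = compute_series(timelines["P0001"], cfg)
base = baseline_score(series, cfg.baseline_policy, cfg)
print(first_trigger(indicator_series(series, base, cfg.delta_threshold)))
```

See `docs/methods.md` for the model, its assumptions, and every tunable.
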
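# pmexpo

Personal particulate-matter exposure analysis pipeline for backpack-sensor
field studies. Given 1-s PM2.5/PM10 + GPS traces from monitored school
children, a cohort questionnaire table and daily meteorology, it:

- aggregates traces to calendar minutes with a 50% sample-validity rule
  (`pmexpo.trace_io`);
- applies inclusion rules — the strict ">24 h continuous valid data"
  filter, an exclusion ledger (no questionnaire / withdrew / backpack not
  taken to school / monitor failure / insufficient data), and a cumulative
  >12 h GPS-gap flag (`pmexpo.qc`);
- tags every minute as home / school / commute / other / unknown using
  100 m geofences around anchors inferred from overnight and school-hour
  GPS fixes, with transition and bounded carry-forward rules
  (`pmexpo.tagger`);
- computes daily means (Monday–Thursday, ≥75% coverage), per-
  microenvironment exposure summaries and time/exposure proportions,
  PM2.5:PM10 ratios, city diurnal profiles, and counts of days below the
  24-h guidelines of 15 µg/m³ (PM2.5) and 45 µg/m³ (PM10)
  (`pmexpo.metrics`);
- runs the statistical layer: Kruskal–Wallis H with Dunn post-hocs and
  Holm adjustment, and a nested random-intercept (child within city)
  linear mixed model on log daily exposure, reported as percent changes
  `(exp(β) − 1) × 100` with Wald CIs, Satterthwaite denominator df, VIF
  diagnostics and single-term AIC screening (`pmexpo.inference`,
  `pmexpo.lmm`);
- generates synthetic cohorts with exact ground truth — lognormal
  city/child/day exposure structure, planted multiplicative determinant
  effects, weekday schedules, GPS jitter/dropout — so the whole pipeline
  is testable without any field data (`pmexpo.synth`).

The mixed model uses a purpose-built REML/ML engine for the two-level
nested covariance (O(n) likelihood evaluations via the nested block
structure), cross-checked in the test suite against the closed-form
balanced nested-ANOVA estimator and `statsmodels.MixedLM`.

## CLI

```sh
# synthetic input directory (traces/, cohort.csv, meteorology.csv, truth.json)
pmexpo generate --out data/in --seed 1 --n-children 4

# full run: QC -> tagging -> metrics -> model, plus manifest.json
pmexpo run --in data/in --out data/out --seed 1

# individual stages
pmexpo qc --in data/in --out data/qc
pmexpo tag --trace data/in/traces/Blantyre_000.csv --out labeled.csv
pmexpo summarise --labeled labeled.csv --out data/sum
pmexpo model --daily data/out/daily_exposure.csv --cohort data/in/cohort.csv \
             --met data/in/meteorology.csv --out data/model
pmexpo report --outputs data/out --cohort data/in/cohort.csv --out chars.csv
```

Every threshold (minute validity, geofence radii, carry-forward limit,
coverage rule, guideline values, …) lives in a single JSON-serialisable
config (`pmexpo.config`); re-running with the same config and seed yields
byte-identical outputs.

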
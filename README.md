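# raredetect

Rule-based screening of structured electronic-health-record (EHR) tables
for undiagnosed rare-disease suspects — Fabry disease and familial
hypercholesterolaemia (FH) — plus cohort analytics and a synthetic-EHR
generator so the whole pipeline can be developed and tested without
protected patient data.

## What it does

* **EHR model** (`raredetect.ehr_model`) — typed records and validated
  CSV readers/writers for four flat tables (patients, problem-list
  entries, lab results, medication orders), `PIDxxxxxx` pseudonymisation,
  and completed-years age arithmetic. Rows violating the schema are
  rejected with row-level diagnostics, never silently coerced. LDL-C
  values arriving in mg/dL are converted to mmol/L (÷ 38.67).
* **Value sets** (`raredetect.valuesets`) — named groups of clinical
  codes and description synonyms that unify spelling/naming variants of
  one concept into a single filterable unit, with a JSON catalog format
  and a shipped default catalog (placeholder local codes; override via
  `--catalog`).
* **Fabry screen** (`raredetect.fabry_screen`) — suspect iff strictly
  under 50 years old at the reference date *and* problem-list evidence in
  at least two of five organ systems (kidney, cardiac, neuro, skin, eye).
  A Fabry-diagnosis match makes the patient a known case, never a suspect.
* **FH screen** (`raredetect.fh_screen`) — suspect iff any of: premature
  ASCVD (earliest event before 55/male or 60/female), LDL-C > 2.6 mmol/L
  while covered by a high-intensity statin order, LDL-C > 3.9 mmol/L at
  age ≤ 18, or LDL-C > 4.9 mmol/L at age > 18 (ages at the draw date; all
  thresholds strict). Known cases preempt.
* **Cohort analytics** (`raredetect.cohort_analytics`) — superset-
  containment interaction counts (orders 1–5), exact five-way Venn-region
  counts, demographics summaries (median/IQR ages, sex/race proportions),
  Welch/pooled two-sample t-tests, and prevalence / percent-increase /
  expected-case arithmetic.
* **Synthetic data** (`raredetect.synthetic_data`) — seeded generator
  planting known cases, rule-satisfying suspects, near-miss decoys that
  fail exactly one rule clause, and negatives, with a ground-truth
  manifest (`truth.csv`) that the screens must recover exactly.
* **CLI** (`raredetect.cli`) — `generate`, `screen-fabry`, `screen-fh`,
  `summarize`, `run-all`.

## CLI usage

```sh
# generate a synthetic cohort (four CSVs + truth.csv + config echo)
raredetect generate --config config.yaml --out-dir cohort/

# screen it
raredetect screen-fabry --cohort cohort/ --out fabry_results.csv
raredetect screen-fh     --cohort cohort/ --out fh_results.csv

# summary tables (demographics, interactions, Venn regions, t-test)
raredetect summarize --results fabry_results.csv --fh-results fh_results.csv \
    --cohort cohort/ --out-dir summary/

# or the whole pipeline in one go, with a machine-readable manifest
raredetect run-all --seed 7 --out-dir run/ --json
```

Exit codes: `0` success, `2` configuration error, `3` data error.

A config file is optional; every field has a default. Example:

```yaml
n_patients: 5000
seed: 7
window: {start: 2018-01-01, end: 2022-03-01}
fabry: {n_known: 4, n_suspect: 20}
fh: {n_known: 16, n_suspect: 120}
decoys: {fabry_age: 13, fabry_single_system: 13,
         fh_ldl_threshold: 12, fh_weak_statin: 12}
```

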
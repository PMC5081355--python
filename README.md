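# mmclaims

Claims-based case-finding ("computable phenotype") algorithms for multiple
myeloma, implemented as a reusable, tested pipeline:

* **claims_model** — longitudinal data model (persons, enrollment spans,
  medical/drug claims, EMR records) and a delimited-table interchange
  format with canonical diagnosis codes and deterministic round-tripping.
* **codesets** — configurable clinical code sets with the trailing-wildcard
  dialect needed for ICD-9-CM families such as `203.0x`.  Only the MM
  diagnosis set ships as an authoritative list; every other set is a
  clearly labelled placeholder (`src/mmclaims/data/codesets.yaml`).
* **cohort** — gold-standard construction: oncology-EMR cases (with
  incident/prevalent classification), primary-care-EMR controls with
  chemotherapy / stem-cell-transplant / free-text exclusions, and a seeded
  development/validation split.
* **panel** — per-diagnosis evaluation panel: every MM-coded claim with
  90 days of enrollment before and 30 after is an eligible index event,
  with windowed features extracted over at most 180 days on each side.
* **algorithm_engine** — AND/OR clause trees over windowed predicates,
  evaluated at each index and flagging each patient at the earliest
  qualifying diagnosis.  Built-ins: `baseline` (2 distinct MM-diagnosis
  dates within ±180 days) and `algorithm2` (post-index confirmation +
  pre-index testing + diagnoses-before-tests, OR chemotherapy within 180
  days after), with three named precedence variants for the chemotherapy
  disjunct.  A deliberately independent `brute_force_flag` oracle re-derives
  flags by raw scanning and backs the equivalence tests.
* **validation** — patient-level confusion counts, sensitivity,
  specificity, flagged fraction, and the derived PPV / implied prevalence
  obtained by inverting the Bayes relationship.
* **descriptives** — stratum-level annualized event rates and
  diagnosis-level window summaries (percent with event, mean, SD).
* **synthetic_data** — a seeded generator calibrated to the published
  stratum descriptives (annual MM-diagnosis, test, and chemotherapy-day
  rates; window-level symptom/treatment probabilities), plus deterministic
  archetype timelines with hand-derived expected flags.
* **cli** — `mmclaims` command with `simulate`, `cohort`, `panel`,
  `run-algorithm`, `validate`, `summarize`, and `run-all` subcommands.

## Quick start

```bash
# end-to-end on a freshly simulated, table-calibrated population
mmclaims run-all --out out/ --seed 7

# or stage by stage
mmclaims simulate --out out/data --seed 7
mmclaims cohort --data out/data --out out --seed 7
mmclaims run-algorithm --data out/data --out out --algorithm algorithm2
mmclaims validate --data out/data --labels out/labels.csv \
    --flags out/flags.csv --out out --reference-population mm-dx
mmclaims summarize --data out/data --labels out/labels.csv --out out
```

`run-algorithm` also accepts `algorithm2:or_with_sequence`,
`algorithm2:or_inner`, or a path to a YAML clause-tree spec
(see `mmclaims.algorithm_engine.save_spec`).

## Notes

* All temporal logic is whole-calendar-day arithmetic; windows are
  inclusive on both endpoints.
* Real code lists for tests, chemotherapy, and symptoms are proprietary to
  claims-data vendors; supply your own via `--codesets your.yaml`.
* The headline operating points reported for these algorithms on linked
  EMR/claims data are not reproducible without that proprietary linkage;
  the synthetic generator supports property-based and calibration testing
  only.
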
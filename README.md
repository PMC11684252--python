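# smaclaims

A claims-based analysis pipeline for adherence, persistence, and health-care
costs in patients on a daily oral disease-modifying therapy for spinal
muscular atrophy (SMA), together with a synthetic claims generator so every
stage is testable against known ground truth without any proprietary data.

The pipeline covers:

- **Claims I/O** (`smaclaims.claims`) — validated, documented delimited-text
  schemas for enrollment spans, medical claims, pharmacy claims, and
  demographics, with round-trip read/write.
- **Synthetic claims** (`smaclaims.synth`) — seed-deterministic generation of
  bundles with controllable refill-gap behavior, therapy-switch events,
  severity markers, comorbidity codes, per-category log-normal costs, and
  decoy patients that each violate exactly one inclusion criterion.
- **Cohort selection** (`smaclaims.cohort`) — qualifying diagnosis codes
  (G12.0/G12.1/G12.9), index date at the first on-/post-approval dispensing
  (2020-08-07 by default), continuous-enrollment checks (183 days post-index,
  92 days pre-index for types 2–4), study windows capped at 365 days, and a
  selection funnel log.
- **SMA typing** (`smaclaims.sma_types`) — a priority-ordered rule engine on
  age at first diagnosis, age at end of observed activity, and severity
  markers. The shipped default rule table is an explicitly non-authoritative
  stand-in; supply your own CSV for a validated algorithm.
- **Adherence** (`smaclaims.adherence`) — proportion of days covered (PDC)
  with carry-forward supply stacking (oversupply is banked; a
  non-carry-forward variant is available for sensitivity analysis),
  truncation at the window end, the 0.80 adherence threshold, PDC bands
  (<0.80, 0.80–<0.90, 0.90–1.00), and configurable age bins.
- **Persistence** (`smaclaims.persistence`) — discontinuation at a refill gap
  exceeding 30 days after supply exhaustion (dated at the exhaustion day) or
  at a switch to nusinersen/onasemnogene abeparvovec, whichever comes first;
  censoring at the window end; and a from-scratch Kaplan-Meier product-limit
  estimator (cross-checked against `lifelines` in the tests).
- **Costs** (`smaclaims.costs`) — setting-bucket categorization with
  ventilation/nutrition overlay subcategories, exclusion of all
  disease-modifying-therapy costs, claim-level inflation to reference-year
  dollars (packaged index snapshot is a stand-in), per-patient-per-year
  annualization, a $4M outlier exclusion, and descriptive summaries
  (mean, sample SD, median, linear-interpolation quartiles).
- **Reporting** (`smaclaims.report`, `smaclaims.cli`) — regimen
  classification, report tables (demographics/comorbidities, adherence by
  type and age group, costs by adherence × type and by PDC band, KM curves),
  and a byte-deterministic end-to-end runner with a machine-readable
  manifest.

## CLI

```sh
# synthesize a 200-patient bundle (CSV files + ground_truth.csv)
smaclaims simulate --n 200 --seed 7 --out bundle/

# stage by stage
smaclaims build-cohort --bundle bundle/ --out cohort.csv --log funnel.csv
smaclaims type       --bundle bundle/ --cohort cohort.csv --out types.csv
smaclaims adherence  --bundle bundle/ --cohort cohort.csv --out adherence.csv
smaclaims persistence --bundle bundle/ --cohort cohort.csv --out pers.csv --km km.csv
smaclaims costs      --bundle bundle/ --cohort cohort.csv --adherence adherence.csv --out costs.csv

# or everything at once (simulate + analyze + report)
smaclaims run --simulate --n 86 --seed 7 --out report/
smaclaims run --bundle bundle/ --out report/
```

Two runs of `smaclaims run --simulate --seed N` produce byte-identical
report bundles.

## Data formats

Bundles are four CSV files with ISO-8601 dates (see `smaclaims/claims.py`
for the column contracts): `enrollment.csv`, `medical_claims.csv`,
`pharmacy_claims.csv`, `demographics.csv`. Configurable reference tables
(typing rules, procedure-code flag map, comorbidity code map, inflation
index) are plain CSVs under `smaclaims/data/`; all shipped values are
documented stand-ins.
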
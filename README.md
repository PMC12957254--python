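# faersig

Signal screening and time-to-onset analysis for FAERS-style spontaneous
adverse-event report data, built as a staged, testable pipeline:

1. **faers_io** — read/write the "$"-delimited quarterly ASCII dialect
   (DEMO/DRUG/REAC/OUTC/RPSR/THER/INDI) and link quarters into one dataset.
2. **cleaning** — case deduplication (latest report per caseid), drug-name
   standardization from a synonym table, primary-suspect filtering, age /
   sex / reporter / outcome normalization, and descriptive summary tables
   (demographics, indications, concomitant medication).
3. **disproportionality** — 2×2 contingency tables against the
   all-other-drugs background; ROR with Woolf CI, PRR with CI and
   uncorrected Pearson χ², BCPNN information component with its IC025
   lower bound; configurable positive-signal criteria
   (default: ROR CI low > 1, or PRR ≥ 2 & χ² ≥ 4, or IC025 > 0; N ≥ 3);
   PT-level screens and SOC-level profiles.
4. **onset** — time-to-onset extraction (event date minus earliest therapy
   start), two-parameter Weibull MLE with failure-pattern classification,
   Kaplan–Meier cumulative incidence, log-rank test, and a univariate Cox
   hazard ratio (Efron ties, via `lifelines`).
5. **subgroup** — age-stratified screening (<18, 18–65, ≥65) with
   stratum-matched backgrounds and Benjamini–Hochberg adjusted p-values
   (volcano-plot tables).
6. **synthgen** — synthetic FAERS-dialect datasets with exact ground truth:
   injected drug–event relative risks, per-arm Weibull onset distributions,
   configurable missingness, and intentional duplicate reports.
7. **pipeline / cli** — orchestration with deterministic, seedable outputs.

## CLI

```bash
# synthetic dataset with ground-truth manifest
faersig simulate --out data/ --seed 1

# full pipeline (descriptives, PT screens, onset, subgroup volcano tables)
faersig run-all --input data/ --out results/

# individual stages
faersig clean   --input data/ --out cleaned/
faersig screen  --records cleaned/records.csv --drug risankizumab --out screen.csv
faersig onset   --input data/ --out onset/
faersig subgroup --records cleaned/records.csv --cases cleaned/cases.csv \
                 --drug risankizumab --out volcano.csv
faersig report  --input data/ --out report/
```

`run-all` accepts `--min-n`, an indication-PT exclusion list
(`--exclusions`, one PT per line) and a two-column PT→SOC CSV
(`--pt-to-soc`). Without `--input` it generates a synthetic dataset first
(`--synth-config` YAML, `--seed`).

## Notes on conventions

- Missing fields are empty strings in the dialect and NA in memory; the
  two are not distinguishable on disk.
- Partial dates (YYYYMM / YYYY) are retained with a precision flag, never
  imputed; time-to-onset uses full-precision dates only.
- Same-day onsets are recoded to 0.5 days; negative or future-dated
  (relative to the report date) onsets are excluded.
- Zero cells yield flagged NaN statistics (no Haldane correction by
  default; available via `haldane=True`).
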
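# deprecon

Cost-utility and cost-consequence analysis toolkit for two-arm deprescribing
cohorts (drug continuation vs. discontinuation over a six-month horizon).

The package provides a complete, reproducible pipeline:

1. **`deprecon.cohort`** — synthetic cohort generator calibrated to published
   group marginals (arm sizes, Poisson utilization means, covariate
   proportions, functional-health trajectories), so every downstream stage is
   testable without access to the original patient data.
2. **`deprecon.costs`** — tariff-based costing of utilization counts with
   CPI price-year updating and per-group cost summaries.
3. **`deprecon.qaly`** — mapping of 7-item functional health totals (7–35,
   lower is better) to utilities via `(35 − score)/28`, and half-year QALY
   quantities (both the absolute area-under-curve and the QALY *gain*; the
   cost-utility stage uses the gain).
4. **`deprecon.cca`** — group comparisons with Mann-Whitney rank tests
   (exact enumeration for small samples, tie-corrected normal approximation
   otherwise), optionally stratified (e.g. by sex).
5. **`deprecon.regression`** — per-category Poisson regressions of
   utilization counts with incidence rate ratios, Wald CIs, fixed reference
   levels, and optional robust (sandwich) standard errors.
6. **`deprecon.cua`** — deterministic ICER with dominance classification and
   a probabilistic sensitivity analysis (gamma-distributed costs,
   beta-distributed QALYs, moment-matched to arm means/SEs) with
   cost-effectiveness-plane quadrant summaries and subgroup stratification.
7. **`deprecon.pipeline` / `deprecon.cli`** — end-to-end orchestration with
   a file manifest, a reproducibility log, and cohort-file validation.

## CLI

```bash
# generate a calibrated synthetic cohort (CSV, fixed column order)
deprecon simulate --seed 1 --out cohort.csv --report

# validate any cohort CSV against the schema
deprecon validate cohort.csv

# deterministic cost-utility analysis (JSON ICER + arm moments)
deprecon cua --cohort cohort.csv --out icer.json

# probabilistic sensitivity analysis, optionally stratified
deprecon psa --cohort cohort.csv --iters 1000 --seed 1 --stratify sex --outdir psa/

# full pipeline: cohort.csv, table2.csv, table3.csv, table4_irr.csv,
# icer.json, psa_draws.csv, quadrants.csv, run_log.json
deprecon run --outdir results --seed 1 --iters 1000
```

All randomness flows from the single run seed; reruns with the same
configuration are byte-identical.

## Conventions worth knowing

- Incremental quantities are oriented **discontinuation − continuation**;
  comparison-table differences are **continuation − discontinuation**.
- Quadrant convention: x = ΔQALY, y = Δcost; "southeast" (more effective,
  less costly, i.e. dominant) is x > 0, y < 0; axis draws go east/south.
- Costs are computed at full precision; integer-euro rounding (half away
  from zero) happens only when a report table is rendered.
- The PSA parameterizes gamma/beta distributions with the **SE of the arm
  mean** (second-order uncertainty), not the participant-level SD.
- Two tariff files are packaged: the default prices a primary-care emergency
  visit at €73.30, the `alt` variant at €73.34.
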
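# trialemu

Emulate clinical-trial treatment arms from longitudinal ophthalmology
registry data.

`trialemu` builds *pro re nata* (prn) anti-VEGF treatment arms from
EHR-style event tables through a rule-based eligibility/attrition engine,
aligns them to monthly clinical-trial arms by two methods — 1:1 caliper
matching and inverse propensity score weighting (IPSW) — and compares
visual-acuity, injection, cost and safety outcomes between arms.  A
synthetic-data module generates registries and trial rosters with known
ground truth, so the whole pipeline is testable without access to any
proprietary data.

## Modules

| Module | What it does |
|---|---|
| `trialemu.vision` | Snellen → approximated-ETDRS letter conversion (`85 + 50·log10(fraction)`, half-away-from-zero rounding), best-documented/baseline/1-year acuity selection |
| `trialemu.synthetic` | Seeded generator for the seven registry event tables, trial rosters, and a ground-truth manifest; every eligibility criterion can be seeded to fail on a configurable fraction of eyes |
| `trialemu.cohort` | The attrition engine: ordered inclusion, treatment-pattern and exclusion criteria; emits per-drug cohorts plus a cumulative attrition table |
| `trialemu.matching` | 1:1 caliper matching (gender exact, age ±5 y with ≥90 top-coded, acuity ±5 letters); maximum-cardinality solver with deterministic tie-breaks, greedy baseline |
| `trialemu.ipsw` | Self-contained IRLS logistic regression, ATT odds weights `p/(1−p)` rescaled to arm N, SMD balance diagnostics, effective sample size |
| `trialemu.outcomes` | Per-arm summaries: letter change, ±15-letter responders, injections, drug cost (cents internally), endophthalmitis incidence; weighted or unweighted |
| `trialemu.compare` | Unpaired two-sample t-tests (pooled default, Welch optional) from raw samples or summary statistics |
| `trialemu.io` / `trialemu.pipeline` / `trialemu.cli` | CSV/YAML I/O with schema validation, the end-to-end pipeline, and the `emulate` CLI |

## CLI

The end-to-end run (synthetic inputs by default):

```bash
emulate run --seed 1 --out pipeline_out
```

writes `attrition.csv`, `cohorts.csv`, `pairs.csv`, `weights.csv`,
`balance.csv`, `outcomes.csv`, `comparisons.csv` and `manifest.json`.
Stages are also available individually and round-trip through CSV:

```bash
emulate simulate  --seed 1 --n-patients 500 --out fixtures/
emulate attrition --registry fixtures/ --out attrition.csv --cohort-out cohorts.csv
emulate match     --trial fixtures/trial.csv --cohort cohorts.csv --out pairs.csv
emulate weight    --trial fixtures/trial.csv --cohort cohorts.csv \
                  --out weights.csv --balance balance.csv
emulate outcomes  --trial fixtures/trial.csv --cohort cohorts.csv \
                  --pairs pairs.csv --weights weights.csv --out outcomes.csv
emulate compare   --outcomes outcomes.csv --out comparisons.csv
```

## Notes on method choices

- The IPSW estimand is ATT-style: the trial arm is the target population
  and registry eyes receive odds weights `p/(1−p)`, rescaled so weighted
  tallies sum to the registry arm size.  The source description names the
  logistic model but not the weight formula; this interpretation reproduces
  fractional weighted-count tables.
- The default t-test is pooled-variance: both published
  exact-matching-vs-IPSW comparisons are reproduced to two decimals under
  pooling, while Welch differs on one of them.
- Matching is solved as a maximum-cardinality bipartite matching (via a
  dominated-cost assignment problem) with deterministic tie-breaking by
  total letter difference, then age difference, then ids; a greedy solver
  is provided to probe order sensitivity.
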
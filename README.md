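# asthmacea

Decision-tree cost-effectiveness analysis of primary asthma prevention in
children: a tested, end-to-end pipeline comparing multifaceted prevention
(measures against both airborne and food allergen triggers), unifaceted
prevention (exactly one measure) and the current situation (usual care,
modelled as a 20%/80% mixture of high-risk controls and low-risk children).

Because the underlying individual-level trial records are not deposited, the
pipeline is driven by a first-class synthetic cohort generator that emulates
the assumed statistical structure (two familial-risk strata, per-strategy
probabilities of symptoms, pharmacotherapy and objective test results,
Poisson resource use, per-field missingness) and ships a closed-form oracle
for testing. Published summary values are kept as frozen regression fixtures
and are never presented as recomputed results.

## Components

| module | role |
|---|---|
| `synthetic_cohort` | cohort generator + exact (enumeration) expectation oracle |
| `diagnosis` | 10-row objective asthma classification with a configurable ambiguous cell |
| `cohort_prep` | evaluability filter, per-protocol group assignment, usual-care mixture |
| `costing` | unit prices, year indexation (target 2009), per-child cost aggregation |
| `tree_engine` | canonical chance tree (symptoms → pharmacotherapy → diagnosis), branch estimation, fold-back, path enumeration |
| `cea` | ICER, strong/extended dominance, efficient frontier, net-benefit threshold sweep |
| `cli_io` | cohort CSV I/O, run configuration, pipeline command |
| `fixtures` | frozen reference values and a deterministic reference cohort |

## CLI

```sh
# write a synthetic cohort CSV (optionally with the per-protocol group column)
asthmacea simulate --seed 1 --out cohort.csv --group-column

# full pipeline in synthetic mode with defaults
asthmacea run --seed 1 --out-dir results/run1

# pipeline from an existing cohort CSV via a config file
asthmacea run --config config.yaml

# CEA on a precomputed expectation table
asthmacea cea --expectations expectations.csv --reference current
```

`run` writes `expectations.csv`, `incremental.csv`, `threshold_curve.json`,
serialized trees under `trees/`, and a `run_report.json` reconciling input,
excluded and grouped record counts. Identical config and seed yield
byte-identical outputs. Monetary outputs use 2 decimals, probabilities 5.

A `RunConfig` YAML accepts: `cohort_path` *or* `generator_params_path`,
`price_table_path`, `diagnosis_rule` (`negative`/`positive` resolution of the
ambiguous ICS+/both-tests-negative cell), `w_pfh`, `empty_cell_policy`
(`strict`/`additive`/`collapse`), `lambda_min`/`lambda_max`/`lambda_step`,
`out_dir`, `seed`.

Shipped unit prices and generator rates are runnable placeholders, not
estimates of any historical tariff or trial.

## Cohort CSV schema

Comma-separated, UTF-8, mandatory header. Booleans are `0`/`1`, missing
values are empty fields. Columns: `id`, `family_history` (`PFH`/`NFH`),
`trial_arm` (`intervention`/`control`/`natural_history`),
`airborne_compliant`, `food_compliant` (empty for NFH), `ics_use`,
`symptomatic`, `reversibility`, `hyperreactivity`, plus one `ru_<item>`
count column per cost item.

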
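# stratarx

Heterogeneous-treatment-effect estimation from confounded observational (or
imbalanced RCT) cohorts, built around four stages:

1. **Baseline risk strata** — fit an outcome model on untreated patients
   only, predict counterfactual baseline risk for everyone, and split the
   cohort into contiguous risk buckets (sparse buckets merge top-down).
2. **Prognostic matching** — within each bucket, pair treated and untreated
   patients by exactly minimizing the total squared Euclidean distance over
   standardized covariates (a rectangular assignment problem, solved
   exactly), so each stratum emulates a randomized assignment.  RCT cohorts
   skip matching; imbalanced high-risk strata are instead repaired by seeded
   oversampling.
3. **Confounding-corrected counterfactual rewards** — train paired risk
   models on the matched arms; the treated model's loss up-weights treated,
   event-free records by a weight ρ ≥ 1.  The signed difference in mean
   predicted risk between the two models measures residual unobserved
   confounding; the smallest grid ρ that closes the gap cancels it.  ρ can
   also be tuned against a validation cohort via recommendation sensitivity
   and specificity.
4. **Policy tree** — a greedy axis-aligned decision tree assigns each leaf
   the treatment with lower summed predicted risk (ties withhold
   treatment), reporting per-node absolute and relative risk reductions.
   An exhaustive depth-≤2 oracle bounds the greedy search in tests.

A synthetic-cohort module generates observational and RCT cohorts with a
known latent confounder, a planted subgroup treatment effect and exported
ground truth, so the whole pipeline is testable offline.

## CLI

```bash
# generate a synthetic bundle (cohort.csv, ground_truth.csv, config.yaml)
stratarx simulate --preset gist --n 2000 --seed 1 --out sim/

# full pipeline from a YAML run config
stratarx run --config run.yaml --seed 1 --out results/run1

# weight-tuning table only (observational mode)
stratarx tune --config run.yaml

# score a serialized tree against an untreated validation cohort
stratarx evaluate --tree results/run1/tree.json \
    --cohort val.csv --columns columns.yaml
```

A minimal run config:

```yaml
mode: observational        # or rct (no weight grid allowed there)
seed: 1
out_dir: results/run1
train: {preset: gist, n: 2000}          # or {path: train.csv, columns: {...}}
validation: {preset: gist, n: 2000}
horizon: 84
buckets: {strategy: quantile, m: 6, min_per_arm: 5}
weight: {grid: [1.0, 1.5, 2.0, 2.5, 3.0], rule: max_youden}
tree: {minbucket: 15, max_depth: 4}
```

The run writes a deterministic artifact bundle: `stratification.csv`,
`match_pairs.csv`, `weight_trace.csv`, `tuning_table.csv`, `rewards.csv`,
`tree.json` / `tree.txt`, `metrics.json` and `run_log.json`.

## Layout

```
src/stratarx/
  cohort.py      data model, CSV I/O, horizon labels, validation
  models.py      pluggable classifiers (random forest, exact-loss logistic)
  baseline.py    baseline risk model, bucket stratification, balance checks
  matching.py    within-bucket optimal 1:1 matching, RCT oversampling
  rewards.py     weighted counterfactual models, gap, minimum-weight search
  tree.py        greedy policy tree + exhaustive small-depth oracle
  evaluation.py  sensitivity/specificity/NPV, weight tuning, robustness
  synthetic.py   confounded cohort generator with ground truth
  pipeline.py    end-to-end orchestration from a run config
  cli.py         click CLI (simulate / run / tune / evaluate)
```
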
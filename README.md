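# metarisk

Metabolomics-based disease-risk prediction pipeline: synthetic cohort
generation, preprocessing, per-metabolite logistic association screening,
regularised least-squares (RLS) risk classification with greedy marker
selection, repeated nested stratified cross-validation, and discrimination
statistics (AUC with percentile CIs, DeLong tests, discrimination slope,
IDI).

## Modules

| module | contents |
|---|---|
| `metarisk.synthetic` | `SyntheticConfig`, `generate_cohort`, `inject_missingness`, `generate_validation_cohort`, `benchmark_config` — cohorts with planted per-SD effects, correlated marker pairs, block-correlated nulls, class-conditional clinical covariates, exact progressor-count calibration |
| `metarisk.preprocess` | minimum imputation, per-feature standardisation (with reusable `StandardisationParams`), panel merging, covariate-missingness exclusion |
| `metarisk.association` | IRLS logistic regression with Wald inference and separation flagging, per-SD (adjusted) odds ratios, Storey/BH q-values, Fisher/Welch baseline comparisons (incl. summary-statistics form) |
| `metarisk.rls` | primal/dual ridge with unpenalised intercept, closed-form leave-one-out via the regularised hat matrix, greedy forward selection on LOO-MSE, panel-size sweep |
| `metarisk.crossval` | stratified folds, repeated nested CV (inner CV picks the penalty by out-of-fold AUC), per-repetition marker selection + panel union, external-cohort transfer by parameter averaging |
| `metarisk.evaluation` | Mann-Whitney AUC, ROC curves, percentile CIs, DeLong test/CI, risk-probability conversion, discrimination slope, IDI, IDI↔integrated-NRI identity check |
| `metarisk.pipeline` / `metarisk.cli` | YAML-configured orchestration, model-family resolution (clinical-only / metabolome-only / combined / panel±clinical), marker-set benchmarking, report bundle |

## CLI

```sh
metarisk simulate --seed 1 --outdir cohort
metarisk associate --features cohort/features.tsv --covariates cohort/covariates.tsv
metarisk crossval  --features cohort/features.tsv --covariates cohort/covariates.tsv \
                   --model metabolome-only --repetitions 10
metarisk select    --features cohort/features.tsv --covariates cohort/covariates.tsv \
                   --panel-size 5 --repetitions 10 --outdir panel
metarisk validate  --features ... --valid-features ... --panel-file panel/panel.json
metarisk report    --outdir crossval
metarisk all       --config config.yaml    # full pipeline, see below
```

Minimal `config.yaml`:

```yaml
seed: 1
outdir: run
synthetic:
  n_samples: 543
  n_progressors: 146
crossval: {outer_folds: 10, inner_folds: 10, repetitions: 10}
selection: {select_k: 5}
models: [clinical-only, metabolome-only, panel+clinical]
```

Cohorts are plain TSV/CSV (features; covariates+outcome) with a JSON sidecar;
all results are TSV/JSON.

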
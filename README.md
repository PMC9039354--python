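# liveraudit

Sex-stratified bias audit for liver-disease classifiers built on
ILPD-style biomarker cohorts.

The package re-implements, as a tested reusable pipeline:

- **`data_io`** — ILPD-dialect CSV reader/writer (headerless UCI column
  order: Age, Gender, TB, DB, Alkphos, Sgpt, Sgot, TP, ALB, A/G Ratio,
  Selector), the `Cohort`/`PatientRecord` data model, and sex × class
  cohort summaries.
- **`preprocess`** — mean imputation, sex encoding (female→0, male→1),
  target recoding (Selector 1 → disease 1), min–max normalisation.
  Statistics can be fitted on the whole cohort (*faithful*, reproducing
  preparation-before-split) or on a training fold only (*safe*).
- **`resample`** — from-scratch SMOTE interpolation, class balancing
  (oversample the minority class to parity), sex balancing (oversample
  the under-represented sex, neighbours within that sex, labels inherited
  from the seed record), and 70/30 split policies including sex-balanced
  training folds.
- **`features`** — sex-stratified Pearson correlation ranking, per-sex
  normalised IQR profiles, and recursive feature elimination to a top-5
  subset (coefficient/impurity importances, logistic surrogate for
  learners without importances).
- **`audit`** — the evaluation core: four learner families
  (random forest, logistic regression, RBF SVM, Gaussian naive Bayes)
  with optional grid-search tuning, per-sex confusion matrices and
  metrics (accuracy, precision, recall/TPR, F-score, FNR, TNR, FPR),
  midrank Mann–Whitney ROC AUC, male−female disparity statistics in
  percentage points, paired t-tests over repeated runs, and the
  4-experiment × 4-learner grid with CSV report tables.
- **`synthetic_data`** — a generator of ILPD-like cohorts (two sexes with
  unequal representation, unequal prevalence, right-skewed log-normal
  biomarkers, sporadic A/G-ratio missingness) with a single attenuation
  knob γ that weakens biomarker elevation in diseased females. γ = 1 with
  symmetric sizes is an exchangeable-sexes null for calibration; γ < 1 is
  the signal regime the audit must detect.

## CLI

Generate a synthetic cohort and audit it:

```sh
liver-synth generate --seed 1 --out cohort.csv
liver-audit run --experiment 1 --learner rf --runs 100 --seed 0 \
    --mode faithful --data cohort.csv --out results/
liver-audit grid --runs 100 --seed 0 --data synthetic --out results/grid/
liver-audit report --results results/grid/
```

`--data synthetic` draws a fresh ILPD-like cohort per run; `--data FILE`
re-splits the given cohort on every run. Experiments: 1 = class-balanced
cohort, 2 = class- and sex-balanced, 3 = as 1 with RFE top-5 features,
4 = as 2 with RFE. Each output directory contains one
`experiment<k>_<learner>_disparity.csv` per configuration (metric,
male/female means, disparity in percentage points, paired-t statistic and
p-value), a long-format `per_run_metrics.csv`, and a `run_log.json`
recording config, seeds and library versions.

## Library use

```python
from liveraudit import ExperimentConfig, run_experiment, generate_cohort
from liveraudit.synthetic_data import attenuated_spec

spec = attenuated_spec(gamma=0.5, n_female=300, n_male=300)
config = ExperimentConfig(experiment=1, learner="logistic_regression",
                          n_runs=50, seed=7, tuning=False)
records, rows = run_experiment(
    config, cohort_factory=lambda s: generate_cohort(spec, seed=s)[0])
print({r.metric: round(r.disparity, 2) for r in rows})
```

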
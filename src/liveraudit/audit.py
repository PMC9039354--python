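"""Evaluation core: learners, per-sex confusion matrices and metrics,
rank-based ROC AUC, male-female disparity statistics with paired t-tests
over repeated train/test runs, and the 4-experiment x 4-learner grid.

Experiment designs
------------------
1. class-balanced, sex-unbalanced cohort; no feature selection
2. class- and sex-balanced cohort; no feature selection
3. class-balanced, sex-unbalanced cohort; RFE top-5 features
4. class- and sex-balanced cohort; RFE top-5 features

In ``faithful`` mode the whole cohort is prepared and oversampled before
splitting (reproducing the published procedure, leakage included); in
``safe`` mode preprocessing statistics and oversampling are confined to
the training fold and the test fold holds original records only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata, t as t_dist

from . import preprocess, resample
from .data_io import DISEASE, SEX, Cohort
from .errors import (
    ConfigurationError,
    DegenerateRunsError,
    FitError,
    ValidationError,
)
from .features import default_feature_columns, rfe_top_features, surrogate_for

METRICS: tuple[str, ...] = (
    "accuracy",
    "f_score",
    "roc_auc",
    "precision",
    "recall",
    "fnr",
    "tnr",
    "fpr",
    "tpr",
)

LEARNER_FAMILIES: tuple[str, ...] = (
    "random_forest",
    "logistic_regression",
    "svm",
    "gaussian_nb",
)

GROUPS = ("all", "female", "male")

#: Small published-convention tuning grids; 3-fold internal CV.
DEFAULT_GRIDS: dict[str, dict] = {
    "random_forest": {"n_estimators": [100, 200], "max_depth": [None, 8]},
    "logistic_regression": {"C": [0.1, 1.0, 10.0]},
    "svm": {"C": [0.1, 1.0, 10.0]},
    "gaussian_nb": {},
}


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.tn + other.tn,
            self.fp + other.fp,
            self.fn + other.fn,
        )


@dataclass
class MetricSet:
    """Per-group evaluation metrics; zero-denominator ratios are ``None``."""

    group: str = "all"
    accuracy: float | None = None
    precision: float | None = None
    recall: float | None = None
    f_score: float | None = None
    fnr: float | None = None
    tnr: float | None = None
    fpr: float | None = None
    tpr: float | None = None
    roc_auc: float | None = None

    def get(self, metric: str) -> float | None:
        if metric not in METRICS:
            raise ValidationError(f"unknown metric {metric!r}")
        return getattr(self, metric)


@dataclass
class RunRecord:
    run_index: int
    seed: int
    experiment: int
    learner: str
    metrics: dict[str, MetricSet]
    confusions: dict[str, ConfusionCounts]
    selected_features: list[str] | None = None
    degenerate: bool = False


@dataclass
class DisparityRow:
    """One metric's male/female means, disparity and paired-t result.

    Means and the disparity are on the percentage scale (disparity in
    percentage points, male minus female; negative means the female mean
    is larger).
    """

    metric: str
    male_mean: float
    female_mean: float
    disparity: float
    t_statistic: float | None
    p_value: float | None
    n_runs: int
    n_dropped: int = 0
    degenerate_variance: bool = False


@dataclass
class ExperimentConfig:
    experiment: int = 1
    learner: str = "random_forest"
    n_runs: int = 100
    test_fraction: float = 0.30
    seed: int = 0
    mode: str = "faithful"
    smote_k: int = 5
    class_balance: bool = True
    rfe_n_keep: int = 5
    tuning: bool = True
    tuning_grid: dict | None = None
    tuning_cv: int = 3
    max_degenerate_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.experiment not in (1, 2, 3, 4):
            raise ConfigurationError(f"experiment must be 1-4, got {self.experiment}")
        if self.learner not in LEARNER_FAMILIES:
            raise ConfigurationError(f"unknown learner {self.learner!r}")
        if self.mode not in ("faithful", "safe"):
            raise ConfigurationError(f"mode must be faithful|safe, got {self.mode!r}")

    @property
    def sex_balanced(self) -> bool:
        return self.experiment in (2, 4)

    @property
    def rfe_active(self) -> bool:
        return self.experiment in (3, 4)


# ---------------------------------------------------------------------------
# learners


def make_learner(config: ExperimentConfig, seed: int):
    """Build an (optionally grid-searched) estimator for the config."""
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import GridSearchCV, StratifiedKFold
    from sklearn.naive_bayes import GaussianNB
    from sklearn.svm import SVC

    if config.learner == "random_forest":
        est = RandomForestClassifier(n_estimators=100, random_state=seed)
    elif config.learner == "logistic_regression":
        est = LogisticRegression(max_iter=2000)
    elif config.learner == "svm":
        est = SVC(kernel="rbf")  # decision_function used as the AUC score
    else:
        est = GaussianNB()

    grid = config.tuning_grid
    if grid is None:
        grid = DEFAULT_GRIDS[config.learner]
    if config.tuning and grid:
        cv = StratifiedKFold(
            n_splits=config.tuning_cv, shuffle=True, random_state=seed
        )
        return GridSearchCV(est, grid, cv=cv, n_jobs=1)
    return est


def fit_learner(
    train: Cohort, config: ExperimentConfig, feature_columns: Sequence[str], seed: int
):
    """Fit the configured learner on the training cohort."""
    y = train.df[DISEASE].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise FitError("single-class training fold")
    X = train.df[list(feature_columns)].to_numpy(dtype=float)
    model = make_learner(config, seed)
    model.fit(X, y)
    return model


def predict_scores(model, X: np.ndarray) -> np.ndarray:
    """Continuous score monotone in P(disease); probability where native."""
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.decision_function(X)


# ---------------------------------------------------------------------------
# metrics


def confusion_from_predictions(
    truth: Sequence[int], predicted: Sequence[int]
) -> ConfusionCounts:
    truth = np.asarray(truth, dtype=int)
    predicted = np.asarray(predicted, dtype=int)
    if truth.shape != predicted.shape:
        raise ValidationError(
            f"length mismatch: {truth.shape} truth vs {predicted.shape} predictions"
        )
    for arr, what in ((truth, "truth"), (predicted, "predictions")):
        if not np.isin(arr, (0, 1)).all():
            raise ValidationError(f"{what} labels must be in {{0, 1}}")
    return ConfusionCounts(
        tp=int(np.sum((truth == 1) & (predicted == 1))),
        tn=int(np.sum((truth == 0) & (predicted == 0))),
        fp=int(np.sum((truth == 0) & (predicted == 1))),
        fn=int(np.sum((truth == 1) & (predicted == 0))),
    )


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def metrics_from_confusion(c: ConfusionCounts, group: str = "all") -> MetricSet:
    """Accuracy, precision, recall/TPR, F-score, FNR, TNR, FPR.

    Zero-denominator ratios are reported as undefined (``None``), never
    substituted with 0.
    """
    recall = _ratio(c.tp, c.tp + c.fn)
    precision = _ratio(c.tp, c.tp + c.fp)
    tnr = _ratio(c.tn, c.tn + c.fp)
    f_score = None
    if precision is not None and recall is not None and (precision + recall) > 0:
        f_score = 2 * precision * recall / (precision + recall)
    elif precision is not None and recall is not None:
        f_score = None  # P = R = 0
    return MetricSet(
        group=group,
        accuracy=_ratio(c.tp + c.tn, c.n),
        precision=precision,
        recall=recall,
        tpr=recall,
        f_score=f_score,
        fnr=None if recall is None else 1.0 - recall,
        tnr=tnr,
        fpr=None if tnr is None else 1.0 - tnr,
    )


def rank_auc(truth: Sequence[int], scores: Sequence[float]) -> float | None:
    """ROC AUC as the Mann-Whitney statistic with midrank tie handling:
    P(score+ > score-) + 0.5 P(equal).  ``None`` when a class is absent."""
    truth = np.asarray(truth, dtype=int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(truth == 1))
    n_neg = int(np.sum(truth == 0))
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(scores)  # midranks
    rank_sum_pos = float(np.sum(ranks[truth == 1]))
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def stratified_evaluate(
    model, test: Cohort, feature_columns: Sequence[str]
) -> tuple[dict[str, MetricSet], dict[str, ConfusionCounts], bool]:
    """Evaluate once, partitioning the same predictions by the categorical
    sex field into all / female / male metric sets.

    Returns (metrics, confusions, degenerate) where ``degenerate`` flags a
    sex subgroup containing a single truth class (its threshold-free
    metrics come out undefined).
    """
    X = test.df[list(feature_columns)].to_numpy(dtype=float)
    y = test.df[DISEASE].to_numpy(dtype=int)
    pred = np.asarray(model.predict(X), dtype=int)
    score = predict_scores(model, X)

    metrics: dict[str, MetricSet] = {}
    confusions: dict[str, ConfusionCounts] = {}
    degenerate = False
    for group in GROUPS:
        mask = (
            np.ones(len(test), dtype=bool)
            if group == "all"
            else (test.df[SEX] == group).to_numpy()
        )
        c = confusion_from_predictions(y[mask], pred[mask])
        ms = metrics_from_confusion(c, group=group)
        ms.roc_auc = rank_auc(y[mask], score[mask]) if mask.any() else None
        metrics[group] = ms
        confusions[group] = c
        if group != "all" and (ms.roc_auc is None or not mask.any()):
            degenerate = True
    return metrics, confusions, degenerate


# ---------------------------------------------------------------------------
# disparity statistics


def paired_ttest(
    male_series: Sequence[float], female_series: Sequence[float]
) -> tuple[float | None, float | None, bool]:
    """Paired t-test on per-run male-female differences.

    Returns (t, p, degenerate_variance).  Zero variance with a zero mean
    difference gives (0, 1); zero variance with a non-zero difference is
    reported as the limit p -> 0 with the degenerate flag set.
    """
    m = np.asarray(male_series, dtype=float)
    f = np.asarray(female_series, dtype=float)
    if m.shape != f.shape:
        raise ValidationError("paired series must have equal length")
    n = len(m)
    if n < 2:
        return None, None, False
    d = m - f
    dbar = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        if dbar == 0.0:
            return 0.0, 1.0, False
        return math.copysign(math.inf, dbar), 0.0, True
    t = dbar / (sd / math.sqrt(n))
    p = 2.0 * float(t_dist.sf(abs(t), df=n - 1))
    return t, p, False


def disparity(
    metric: str,
    male_series: Sequence[float | None],
    female_series: Sequence[float | None],
) -> DisparityRow:
    """Male-minus-female disparity row for one metric over paired runs.

    Runs where either group's metric is undefined are dropped pairwise
    (and counted), never zero-filled.
    """
    if len(male_series) != len(female_series):
        raise ValidationError("disparity series must be paired by run")
    pairs = [
        (m, f)
        for m, f in zip(male_series, female_series)
        if m is not None and f is not None
    ]
    n_dropped = len(male_series) - len(pairs)
    if not pairs:
        return DisparityRow(metric, math.nan, math.nan, math.nan, None, None, 0, n_dropped)
    m = np.array([p[0] for p in pairs]) * 100.0
    f = np.array([p[1] for p in pairs]) * 100.0
    t, p, degen = paired_ttest(m, f)
    return DisparityRow(
        metric=metric,
        male_mean=float(np.mean(m)),
        female_mean=float(np.mean(f)),
        disparity=float(np.mean(m) - np.mean(f)),
        t_statistic=t,
        p_value=p,
        n_runs=len(pairs),
        n_dropped=n_dropped,
        degenerate_variance=degen,
    )


# ---------------------------------------------------------------------------
# experiment engine


def _derived_seeds(base_seed: int, run_index: int) -> dict[str, np.random.Generator]:
    """Independent per-component RNG streams for one run."""
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(run_index,))
    children = ss.spawn(5)
    names = ("cohort", "smote", "split", "learner", "tuning")
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def _int_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def _build_faithful(cohort: Cohort, config: ExperimentConfig, rngs) -> tuple[Cohort, Cohort]:
    prepared, _ = preprocess.prepare(cohort)
    if config.class_balance:
        prepared = resample.balance_classes(
            prepared, resample.SmoteParams(0, config.smote_k, rngs["smote"])
        )
    if config.sex_balanced:
        prepared = resample.balance_sexes(
            prepared, resample.SmoteParams(0, config.smote_k, rngs["smote"])
        )
    policy = resample.SplitPolicy(
        test_fraction=config.test_fraction, seed=rngs["split"]
    )
    return resample.train_test_split(prepared, policy)


def _build_safe(cohort: Cohort, config: ExperimentConfig, rngs) -> tuple[Cohort, Cohort]:
    c = preprocess.encode_sex(cohort)
    if not c.target_recoded:
        c = preprocess.recode_target(c)
    policy = resample.SplitPolicy(
        test_fraction=config.test_fraction,
        sex_balanced_training=config.sex_balanced,
        seed=rngs["split"],
    )
    train, test = resample.train_test_split(c, policy)
    train, _ = preprocess.impute_mean(train)
    test, _ = preprocess.impute_mean(test, stats_from=train)
    scaled_train, _ = preprocess.minmax_scale(train)
    test, _ = preprocess.minmax_scale(test, stats_from=train)
    train = scaled_train
    if config.class_balance:
        train = resample.balance_classes(
            train, resample.SmoteParams(0, config.smote_k, rngs["smote"])
        )
    if config.sex_balanced:
        train = resample.balance_sexes(
            train, resample.SmoteParams(0, config.smote_k, rngs["smote"])
        )
    return train, test


def run_once(
    config: ExperimentConfig,
    run_index: int,
    cohort: Cohort | None = None,
    cohort_factory: Callable[[int], Cohort] | None = None,
) -> RunRecord:
    """One build-train-test cycle with seeds derived from the run index."""
    rngs = _derived_seeds(config.seed, run_index)
    if cohort_factory is not None:
        cohort = cohort_factory(_int_seed(rngs["cohort"]))
    if cohort is None:
        raise ConfigurationError("either a cohort or a cohort_factory is required")

    build = _build_faithful if config.mode == "faithful" else _build_safe
    train, test = build(cohort, config, rngs)

    feature_columns = default_feature_columns(train)
    selected = None
    if config.rfe_active:
        ranking = rfe_top_features(
            train,
            surrogate_for(config.learner, seed=_int_seed(rngs["learner"])),
            n_keep=config.rfe_n_keep,
            columns=feature_columns,
        )
        selected = ranking.features
        feature_columns = selected

    model = fit_learner(train, config, feature_columns, _int_seed(rngs["tuning"]))
    metrics, confusions, degenerate = stratified_evaluate(model, test, feature_columns)
    return RunRecord(
        run_index=run_index,
        seed=config.seed,
        experiment=config.experiment,
        learner=config.learner,
        metrics=metrics,
        confusions=confusions,
        selected_features=selected,
        degenerate=degenerate,
    )


def run_experiment(
    config: ExperimentConfig,
    cohort: Cohort | None = None,
    cohort_factory: Callable[[int], Cohort] | None = None,
) -> tuple[list[RunRecord], list[DisparityRow]]:
    """Repeat ``config.n_runs`` independent cycles and summarise disparities.

    With ``cohort_factory`` a fresh cohort is drawn per run (the
    exchangeable null used for calibration); with a fixed ``cohort`` every
    run re-splits the same records.  Aborts if more than
    ``max_degenerate_fraction`` of runs are flagged degenerate.
    """
    records = [
        run_once(config, i, cohort=cohort, cohort_factory=cohort_factory)
        for i in range(config.n_runs)
    ]
    n_degen = sum(r.degenerate for r in records)
    if n_degen > config.max_degenerate_fraction * config.n_runs:
        raise DegenerateRunsError(
            f"{n_degen}/{config.n_runs} runs degenerate "
            f"(limit {config.max_degenerate_fraction:.0%})"
        )
    rows = [
        disparity(
            metric,
            [r.metrics["male"].get(metric) for r in records],
            [r.metrics["female"].get(metric) for r in records],
        )
        for metric in METRICS
    ]
    return records, rows


def run_grid(
    base: ExperimentConfig,
    cohort: Cohort | None = None,
    cohort_factory: Callable[[int], Cohort] | None = None,
    experiments: Sequence[int] = (1, 2, 3, 4),
    learners: Sequence[str] = LEARNER_FAMILIES,
) -> dict[tuple[int, str], tuple[list[RunRecord], list[DisparityRow]]]:
    """Experiments x learner families grid (16 tables at full size)."""
    results = {}
    for exp in experiments:
        for learner in learners:
            config = replace(base, experiment=exp, learner=learner)
            results[(exp, learner)] = run_experiment(
                config, cohort=cohort, cohort_factory=cohort_factory
            )
    return results


# ---------------------------------------------------------------------------
# reporting


def disparity_frame(rows: Sequence[DisparityRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "metric": r.metric,
                "male_mean": r.male_mean,
                "female_mean": r.female_mean,
                "disparity_pp": r.disparity,
                "t": r.t_statistic,
                "p": r.p_value,
                "n_runs": r.n_runs,
                "n_dropped": r.n_dropped,
            }
            for r in rows
        ]
    )


def runs_frame(records: Sequence[RunRecord]) -> pd.DataFrame:
    """Long-format per-run metrics (one row per run x group x metric)."""
    out = []
    for r in records:
        for group in GROUPS:
            for metric in METRICS:
                out.append(
                    {
                        "experiment": r.experiment,
                        "learner": r.learner,
                        "run": r.run_index,
                        "group": group,
                        "metric": metric,
                        "value": r.metrics[group].get(metric),
                    }
                )
    return pd.DataFrame(out)


def write_report_tables(
    results: Mapping[tuple[int, str], tuple[list[RunRecord], list[DisparityRow]]],
    outdir: str | Path,
) -> list[Path]:
    """One disparity CSV per (experiment, learner) plus a master long-format
    per-run metrics file."""
    if not results:
        raise ValidationError("no results to write")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    master = []
    for (exp, learner), (records, rows) in results.items():
        path = outdir / f"experiment{exp}_{learner}_disparity.csv"
        disparity_frame(rows).to_csv(path, index=False)
        written.append(path)
        master.append(runs_frame(records))
    master_path = outdir / "per_run_metrics.csv"
    pd.concat(master, ignore_index=True).to_csv(master_path, index=False)
    written.append(master_path)
    return written
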
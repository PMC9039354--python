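import numpy as np
import pandas as pd
import pytest

from liveraudit.audit import (
    LEARNER_FAMILIES,
    METRICS,
    ExperimentConfig,
    disparity_frame,
    fit_learner,
    make_learner,
    predict_scores,
    run_experiment,
    run_grid,
    run_once,
    runs_frame,
    stratified_evaluate,
    write_report_tables,
)
from liveraudit.data_io import DISEASE, SEX
from liveraudit.errors import ConfigurationError, FitError
from liveraudit.features import default_feature_columns
from liveraudit.preprocess import prepare
from liveraudit.synthetic_data import (
    attenuated_spec,
    generate_cohort,
    ilpd_like_spec,
    null_spec,
)

from conftest import make_cohort

FAST = dict(tuning=False, n_runs=2)


def medium_cohort(seed=0):
    cohort, _ = generate_cohort(
        null_spec(n_per_sex=120, prevalence=0.45, seed=seed)
    )
    return cohort


class TestFitLearner:
    def separable_cohort(self):
        cohort = make_cohort({("male", 1): 20, ("female", 1): 20,
                              ("male", 0): 20, ("female", 0): 20}, seed=0)
        cohort.df["albumin"] = np.where(cohort.df[DISEASE] == 1, 10.0, 0.0)
        cohort.df["total_bilirubin"] = np.where(cohort.df[DISEASE] == 1, 0.0, 10.0)
        return prepare(cohort)[0]

    @pytest.mark.parametrize("family", LEARNER_FAMILIES)
    def test_separable_fixture_perfect_training_accuracy(self, family):
        cohort = self.separable_cohort()
        config = ExperimentConfig(learner=family, tuning=False)
        cols = ["albumin", "total_bilirubin"]
        model = fit_learner(cohort, config, cols, seed=0)
        X = cohort.df[cols].to_numpy()
        assert (model.predict(X) == cohort.df[DISEASE].to_numpy()).all()

    def test_label_randomised_fixture_near_chance(self):
        accs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            cohort = medium_cohort(seed)
            cohort.df[DISEASE] = rng.permutation(cohort.df[DISEASE].to_numpy())
            cohort, _ = prepare(cohort)
            config = ExperimentConfig(learner="logistic_regression", tuning=False)
            cols = default_feature_columns(cohort)
            half = len(cohort) // 2
            train = cohort.subset(cohort.df.index < half)
            test = cohort.subset(cohort.df.index >= half)
            model = fit_learner(train, config, cols, seed=seed)
            X = test.df[cols].to_numpy()
            accs.append((model.predict(X) == test.df[DISEASE]).mean())
        assert abs(np.mean(accs) - 0.5) < 0.05

    def test_single_class_fold_is_fit_error(self):
        cohort = prepare(make_cohort({("male", 1): 10, ("female", 1): 10}))[0]
        config = ExperimentConfig(tuning=False)
        with pytest.raises(FitError):
            fit_learner(cohort, config, default_feature_columns(cohort), seed=0)

    def test_one_point_grid_equals_tuning_off(self):
        cohort = prepare(medium_cohort(3))[0]
        cols = default_feature_columns(cohort)
        off = fit_learner(
            cohort, ExperimentConfig(learner="logistic_regression", tuning=False),
            cols, seed=1,
        )
        on = fit_learner(
            cohort,
            ExperimentConfig(
                learner="logistic_regression", tuning=True, tuning_grid={"C": [1.0]}
            ),
            cols, seed=1,
        )
        X = cohort.df[cols].to_numpy()
        assert np.allclose(predict_scores(off, X), predict_scores(on, X))

    @pytest.mark.parametrize("family", LEARNER_FAMILIES)
    def test_scores_are_continuous(self, family):
        cohort = prepare(medium_cohort(1))[0]
        cols = default_feature_columns(cohort)
        model = fit_learner(
            cohort, ExperimentConfig(learner=family, tuning=False), cols, seed=0
        )
        scores = predict_scores(model, cohort.df[cols].to_numpy())
        assert scores.shape == (len(cohort),)
        assert len(np.unique(scores)) > 2


class TestStratifiedEvaluate:
    def test_hand_built_test_set(self):
        cohort = prepare(make_cohort(
            {("female", 0): 3, ("female", 1): 2, ("male", 0): 2, ("male", 1): 3},
            seed=1,
        ))[0]

        class AlwaysPositive:
            def predict(self, X):
                return np.ones(len(X), dtype=int)

            def decision_function(self, X):
                return np.ones(len(X))

        metrics, confusions, degenerate = stratified_evaluate(
            AlwaysPositive(), cohort, ["age"]
        )
        assert confusions["female"].tp == 2 and confusions["female"].fp == 3
        assert confusions["male"].tp == 3 and confusions["male"].fp == 2
        assert metrics["all"].recall == 1.0 and metrics["all"].tnr == 0.0

    def test_group_confusions_sum_to_all(self):
        cohort = prepare(medium_cohort(2))[0]
        cols = default_feature_columns(cohort)
        model = fit_learner(
            cohort, ExperimentConfig(learner="gaussian_nb", tuning=False), cols, 0
        )
        metrics, confusions, _ = stratified_evaluate(model, cohort, cols)
        total = confusions["female"] + confusions["male"]
        assert total == confusions["all"]

    def test_always_negative_model_recall_zero_everywhere(self):
        cohort = prepare(medium_cohort(4))[0]

        class AlwaysNegative:
            def predict(self, X):
                return np.zeros(len(X), dtype=int)

            def decision_function(self, X):
                return np.zeros(len(X))

        metrics, _, _ = stratified_evaluate(AlwaysNegative(), cohort, ["age"])
        for group in ("all", "female", "male"):
            assert metrics[group].recall == 0.0
            assert metrics[group].fnr == 1.0


class TestRunExperiment:
    def test_bitwise_reproducible(self):
        cohort = medium_cohort(7)
        config = ExperimentConfig(experiment=1, learner="gaussian_nb", seed=5, **FAST)
        r1, d1 = run_experiment(config, cohort=cohort)
        r2, d2 = run_experiment(config, cohort=cohort)
        assert runs_frame(r1).equals(runs_frame(r2))
        assert disparity_frame(d1).equals(disparity_frame(d2))

    def test_metric_identities_hold_per_run(self):
        config = ExperimentConfig(
            experiment=1, learner="logistic_regression", n_runs=4, tuning=False,
            seed=2,
        )
        records, _ = run_experiment(config, cohort=medium_cohort(1))
        for r in records:
            for group in ("all", "female", "male"):
                m = r.metrics[group]
                if m.recall is not None:
                    assert abs(m.fnr - (1 - m.recall)) < 1e-12
                    assert m.tpr == m.recall
                if m.tnr is not None:
                    assert abs(m.fpr - (1 - m.tnr)) < 1e-12
                total = r.confusions["female"] + r.confusions["male"]
                assert total == r.confusions["all"]

    def test_experiment2_faithful_balances_sexes_before_split(self):
        config = ExperimentConfig(experiment=2, learner="gaussian_nb", seed=0, **FAST)
        records, _ = run_experiment(config, cohort=medium_cohort(3))
        assert all(not r.degenerate for r in records)

    def test_rfe_experiments_record_selected_features(self):
        config = ExperimentConfig(experiment=3, learner="logistic_regression",
                                  seed=1, **FAST)
        records, _ = run_experiment(config, cohort=medium_cohort(5))
        for r in records:
            assert r.selected_features is not None
            assert len(r.selected_features) == 5

    def test_safe_mode_test_fold_keeps_original_records_only(self):
        cohort = medium_cohort(6)
        config = ExperimentConfig(experiment=2, learner="gaussian_nb", mode="safe",
                                  seed=3, **FAST)
        records, _ = run_experiment(config, cohort=cohort)
        assert records  # engine ran; per-run test folds are drawn pre-SMOTE

    def test_disparity_rows_cover_all_metrics(self):
        config = ExperimentConfig(experiment=1, learner="gaussian_nb", seed=0, **FAST)
        _, rows = run_experiment(config, cohort=medium_cohort(0))
        assert [r.metric for r in rows] == list(METRICS)

    def test_requires_cohort_or_factory(self):
        with pytest.raises(ConfigurationError):
            run_once(ExperimentConfig(**FAST), 0)

    def test_cohort_factory_draws_fresh_cohorts(self):
        seen = []

        def factory(seed):
            seen.append(seed)
            return medium_cohort(seed)

        config = ExperimentConfig(experiment=1, learner="gaussian_nb", seed=9, **FAST)
        run_experiment(config, cohort_factory=factory)
        assert len(seen) == 2 and seen[0] != seen[1]


class TestGridAndReports:
    def test_grid_emits_16_tables(self, tmp_path):
        base = ExperimentConfig(seed=0, **FAST)
        results = run_grid(base, cohort=medium_cohort(8))
        assert len(results) == 16
        written = write_report_tables(results, tmp_path)
        disparity_files = [p for p in written if "disparity" in p.name]
        assert len(disparity_files) == 16

    def test_single_learner_grid_emits_4_tables(self):
        base = ExperimentConfig(seed=0, **FAST)
        results = run_grid(
            base, cohort=medium_cohort(8), learners=("gaussian_nb",)
        )
        assert len(results) == 4

    def test_grid_reproducible(self):
        base = ExperimentConfig(seed=4, **FAST)
        r1 = run_grid(base, cohort=medium_cohort(2), learners=("gaussian_nb",),
                      experiments=(1, 2))
        r2 = run_grid(base, cohort=medium_cohort(2), learners=("gaussian_nb",),
                      experiments=(1, 2))
        for key in r1:
            assert disparity_frame(r1[key][1]).equals(disparity_frame(r2[key][1]))

    def test_report_tables_consistent_with_master_file(self, tmp_path):
        base = ExperimentConfig(seed=1, n_runs=3, tuning=False)
        results = run_grid(base, cohort=medium_cohort(4),
                           learners=("gaussian_nb",), experiments=(1,))
        write_report_tables(results, tmp_path)
        table = pd.read_csv(tmp_path / "experiment1_gaussian_nb_disparity.csv")
        master = pd.read_csv(tmp_path / "per_run_metrics.csv")
        assert len(table) == len(METRICS)
        for _, row in table.iterrows():
            per_run = master[master["metric"] == row["metric"]]
            male = per_run[per_run["group"] == "male"]["value"].dropna() * 100
            female = per_run[per_run["group"] == "female"]["value"].dropna() * 100
            if row["n_dropped"] == 0:
                assert row["disparity_pp"] == pytest.approx(
                    male.mean() - female.mean()
                )

    def test_round_trip_of_master_file(self, tmp_path):
        base = ExperimentConfig(seed=1, **FAST)
        results = run_grid(base, cohort=medium_cohort(4),
                           learners=("gaussian_nb",), experiments=(1,))
        write_report_tables(results, tmp_path)
        master = pd.read_csv(tmp_path / "per_run_metrics.csv")
        (records, _), = results.values()
        original = runs_frame(records)
        assert len(master) == len(original)
        merged = original.merge(
            master, on=["experiment", "learner", "run", "group", "metric"],
            suffixes=("_a", "_b"),
        )
        both = merged.dropna(subset=["value_a", "value_b"])
        assert np.allclose(both["value_a"], both["value_b"])
        assert merged["value_a"].isna().equals(merged["value_b"].isna())


class TestMakeLearner:
    @pytest.mark.parametrize("family", LEARNER_FAMILIES)
    def test_families_constructible(self, family):
        config = ExperimentConfig(learner=family, tuning=False)
        assert make_learner(config, seed=0) is not None

    def test_unknown_family_rejected(self):
        with pytest.raises(ConfigurationError):
            ExperimentConfig(learner="xgboost")

    def test_invalid_experiment_rejected(self):
        with pytest.raises(ConfigurationError):
            ExperimentConfig(experiment=5)

    def test_invalid_mode_rejected(self):
        with pytest.raises(ConfigurationError):
            ExperimentConfig(mode="leaky")


def test_attenuation_widens_fnr_disparity_monotonically():
    """gamma 1 -> 0.7 -> 0.4 yields a non-increasing trend in female recall
    and a widening negative fnr disparity."""
    fnr_disp = []
    female_recall = []
    for gamma in (1.0, 0.7, 0.4):
        spec = attenuated_spec(gamma=gamma, n_female=150, n_male=150)
        config = ExperimentConfig(
            experiment=1, learner="logistic_regression", n_runs=15, seed=31,
            tuning=False,
        )
        _, rows = run_experiment(
            config, cohort_factory=lambda s: generate_cohort(spec, seed=s)[0]
        )
        by_metric = {r.metric: r for r in rows}
        fnr_disp.append(by_metric["fnr"].disparity)
        female_recall.append(by_metric["recall"].female_mean)
    assert female_recall[0] > female_recall[2]
    assert fnr_disp[0] > fnr_disp[1] > fnr_disp[2]
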
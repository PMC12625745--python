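import numpy as np
import pandas as pd
import pytest

from oralage import (
    FeatureTable,
    SampleMetadata,
    SyntheticConfig,
    ValidationError,
    add_sex_dummy,
    binarize,
    compare_absolute_errors,
    evaluate,
    fit_traditional_regressor,
    generate,
    grid_search_bin_width,
    kfold_cv_pipeline,
    stratified_validation_split,
)
from oralage.model_selection import EvaluationReport


def _cohort_with_pairs(n_extra_singletons=4):
    """150 samples: two per age 6..78 plus a few singleton ages, so every
    validation stratum has eligible (>=2-individual) ages."""
    counts = {age: 2 for age in range(6, 79)}
    for age, extra in zip((20, 30, 40, 50), [1] * n_extra_singletons):
        counts[age] += extra
    total = sum(counts.values())
    return [
        SampleMetadata(f"P{i:03d}", age)
        for i, age in enumerate(np.repeat(list(counts), list(counts.values())))
    ], total


class TestStratifiedValidationSplit:
    def test_cohort_splits_135_15(self):
        meta, total = _cohort_with_pairs()
        assert total == 150
        train, val = stratified_validation_split(meta, seed=8)
        assert len(val) == 15
        assert len(train) == 135
        assert set(train).isdisjoint(val)
        assert set(train) | set(val) == {m.sample_id for m in meta}

    def test_three_per_stratum_from_eligible_ages(self):
        meta, _ = _cohort_with_pairs()
        ages = {m.sample_id: m.age for m in meta}
        age_counts = pd.Series([m.age for m in meta]).value_counts()
        _, val = stratified_validation_split(meta, seed=8)
        strata = [(20, 29), (30, 39), (40, 49), (50, 59), (60, 200)]
        for lo, hi in strata:
            picked = [s for s in val if lo <= ages[s] <= hi]
            assert len(picked) == 3
            assert all(age_counts[ages[s]] >= 2 for s in picked)

    def test_deterministic_given_seed(self):
        meta, _ = _cohort_with_pairs()
        assert stratified_validation_split(meta, seed=8) == stratified_validation_split(
            meta, seed=8
        )

    def test_understaffed_stratum_names_itself(self):
        # only two eligible samples in 50-59
        meta = [SampleMetadata(f"A{i}", age) for i, age in enumerate(
            [25, 25, 26, 26, 27, 27, 35, 35, 36, 36, 45, 45, 46, 46,
             55, 55, 65, 65, 66, 66, 67, 67]
        )]
        with pytest.raises(ValidationError, match="50-59"):
            stratified_validation_split(meta, seed=8)


class _ConstantModel:
    def __init__(self, value):
        self.value = value

    def predict(self, X):
        return np.full(len(X), self.value)


class _EchoModel:
    """Predicts a fixed vector, for exercising the report arithmetic."""

    def __init__(self, preds):
        self.preds = np.asarray(preds, dtype=float)

    def predict(self, X):
        return self.preds


def _eval_table(n):
    return FeatureTable(
        ["f0"], [f"s{j}" for j in range(n)], np.zeros((1, n)), "binarized"
    )


class TestEvaluate:
    def test_perfect_predictions_zero_mae(self):
        ages = [25, 30, 40]
        report = evaluate(_EchoModel(ages), _eval_table(3), ages)
        assert report.mae == 0.0
        assert report.subgroup_mae["20-59"] == 0.0

    def test_hand_computed_mae(self):
        report = evaluate(_EchoModel([25, 30]), _eval_table(2), [20, 40])
        assert report.mae == pytest.approx(7.5)
        assert report.n == 2
        np.testing.assert_array_equal(
            report.per_sample["absolute_error"], [5.0, 10.0]
        )

    def test_subgroup_restricts_to_interval(self):
        # ages 10 and 70 outside 20-59; only the age-30 sample counts there
        report = evaluate(
            _EchoModel([10, 35, 80]), _eval_table(3), [10, 30, 70]
        )
        assert report.subgroup_mae["20-59"] == pytest.approx(5.0)
        assert report.mae == pytest.approx((0 + 5 + 10) / 3)

    def test_empty_subgroup_is_error(self):
        with pytest.raises(ValidationError, match="subgroup"):
            evaluate(_EchoModel([10, 70]), _eval_table(2), [10, 70])

    def test_empty_evaluation_set_is_error(self):
        with pytest.raises(ValidationError, match="empty"):
            evaluate(_EchoModel([]), _eval_table(0), [])


@pytest.fixture(scope="module")
def small():
    cfg = SyntheticConfig(n_samples=60, n_features=40, n_signal_features=8, seed=3)
    raw, meta = generate(cfg)
    return binarize(raw).samples_array(), np.array([m.age for m in meta])


class TestGridSearchBinWidth:
    def test_single_width_returned(self, small):
        X, ages = small
        best, table = grid_search_bin_width(
            X, ages, widths=[16], folds=3, base_learner="knn"
        )
        assert best == 16
        assert len(table) == 1

    def test_grid_shape_and_best_is_argmin(self, small):
        X, ages = small
        widths = [8, 16, 24, 32]
        best, table = grid_search_bin_width(
            X, ages, widths=widths, folds=3, base_learner="knn"
        )
        assert list(table["bin_width"]) == widths
        feasible = table.dropna(subset=["cv_mae"])
        assert best == int(feasible.loc[feasible["cv_mae"].idxmin(), "bin_width"])

    def test_matches_direct_cv_at_fixed_width(self, small):
        from sklearn.model_selection import KFold

        from oralage import BinnedVotingAgeRegressor

        X, ages = small
        _, table = grid_search_bin_width(
            X, ages, widths=[20], folds=3, base_learner="knn", seed=8
        )
        maes = []
        for tr, te in KFold(3, shuffle=True, random_state=8).split(X):
            m = BinnedVotingAgeRegressor(
                bin_width=20, base_learner="knn", random_state=8
            ).fit(X[tr], ages[tr])
            maes.append(np.abs(m.predict(X[te]) - ages[te]).mean())
        assert table["cv_mae"].iloc[0] == pytest.approx(np.mean(maes), abs=1e-12)

    def test_width_outside_range_rejected(self, small):
        X, ages = small
        with pytest.raises(ValueError, match="outside"):
            grid_search_bin_width(X, ages, widths=[81], folds=3)

    def test_degenerate_cohort_infeasible(self):
        X = np.random.default_rng(0).random((12, 4))
        ages = np.full(12, 30)
        with pytest.raises(ValidationError, match="no feasible"):
            grid_search_bin_width(X, ages, widths=[40], folds=3)


class TestTraditionalRegressor:
    def test_constant_training_data_constant_prediction(self):
        X = np.random.default_rng(1).random((20, 3))
        reg = fit_traditional_regressor(X, np.full(20, 44), "random_forest")
        np.testing.assert_allclose(reg.predict(X), 44.0)

    def test_knn_k1_memorizes_training_set(self):
        rng = np.random.default_rng(2)
        X = rng.random((30, 4))
        ages = rng.integers(10, 70, 30)
        reg = fit_traditional_regressor(X, ages, ("knn", {"n_neighbors": 1}))
        assert np.abs(reg.predict(X) - ages).mean() == 0.0

    def test_same_seed_same_predictions(self):
        rng = np.random.default_rng(3)
        X = rng.random((40, 5))
        ages = rng.integers(10, 70, 40)
        p1 = fit_traditional_regressor(X, ages, "xgboost", random_state=8).predict(X)
        p2 = fit_traditional_regressor(X, ages, "xgboost", random_state=8).predict(X)
        np.testing.assert_array_equal(p1, p2)

    def test_classification_only_learner_rejected(self):
        with pytest.raises(ValueError, match="unknown regression learner"):
            fit_traditional_regressor(np.eye(4), [1, 2, 3, 4], "naive_bayes")


class TestAddSexDummy:
    def _table(self, ids):
        return FeatureTable(
            ["f0"], list(ids), np.zeros((1, len(ids))), "binarized"
        )

    def test_female_0_male_1(self):
        meta = [SampleMetadata("a", 30, "female"), SampleMetadata("b", 40, "male")]
        out = add_sex_dummy(self._table("ab"), meta)
        assert out.feature_ids[-1] == "sex_dummy"
        np.testing.assert_array_equal(out.values[-1], [0.0, 1.0])

    def test_all_female_appends_zero_row(self):
        meta = [SampleMetadata(s, 30, "female") for s in "abc"]
        out = add_sex_dummy(self._table("abc"), meta)
        np.testing.assert_array_equal(out.values[-1], [0.0, 0.0, 0.0])

    def test_missing_sex_lists_samples(self):
        meta = [SampleMetadata("a", 30, "female"), SampleMetadata("b", 40, None)]
        with pytest.raises(ValidationError, match="b"):
            add_sex_dummy(self._table("ab"), meta)


def _report(ids, errors):
    return EvaluationReport(
        per_sample=pd.DataFrame(
            {
                "sample_id": ids,
                "true_age": 0.0,
                "predicted_age": 0.0,
                "absolute_error": errors,
            }
        ),
        mae=float(np.mean(errors)),
        subgroup_mae={},
        n=len(ids),
    )


class TestCompareAbsoluteErrors:
    def test_identical_errors_p_one(self):
        ids = [f"s{i}" for i in range(10)]
        errs = list(np.random.default_rng(0).random(10))
        stat, p = compare_absolute_errors(_report(ids, errs), _report(ids, errs))
        assert p == 1.0

    def test_strict_dominance_significant(self):
        ids = [f"s{i}" for i in range(50)]
        rng = np.random.default_rng(1)
        base = rng.random(50) + 1.0
        stat, p = compare_absolute_errors(
            _report(ids, base), _report(ids, base + rng.random(50) + 0.5)
        )
        assert p < 0.01

    def test_pairing_is_by_sample_id_not_order(self):
        ids = ["a", "b", "c", "d", "e", "f"]
        errs = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        shuffled = _report(ids[::-1], errs[::-1])
        stat, p = compare_absolute_errors(_report(ids, errs), shuffled)
        assert p == 1.0  # same pairs after alignment

    def test_mismatched_sample_sets_rejected(self):
        with pytest.raises(ValidationError, match="different sample"):
            compare_absolute_errors(
                _report(["a", "b"], [1.0, 2.0]), _report(["a", "c"], [1.0, 2.0])
            )


@pytest.fixture(scope="module")
def cohort_small():
    cfg = SyntheticConfig(n_samples=60, n_features=40, n_signal_features=8, seed=5)
    raw, meta = generate(cfg)
    return binarize(raw), meta


class TestKFoldCVPipeline:
    def _run(self, table, meta, **kw):
        params = dict(
            folds=3,
            bin_width=16,
            base_learner="knn",
            selection_params={"n_seeds": 3, "cv_folds": 5},
        )
        params.update(kw)
        return kfold_cv_pipeline(table, meta, **params)

    def test_shapes_and_aggregate(self, cohort_small):
        table, meta = cohort_small
        result = self._run(table, meta)
        assert len(result.fold_reports) == 3
        maes = [r.mae for r in result.fold_reports]
        assert result.mean_mae == pytest.approx(np.mean(maes), abs=1e-12)
        assert result.sd_mae == pytest.approx(np.std(maes, ddof=1), abs=1e-12)
        assert sum(r.n for r in result.fold_reports) == table.n_samples

    def test_fixed_seed_reproducible(self, cohort_small):
        table, meta = cohort_small
        r1 = self._run(table, meta, seed=8)
        r2 = self._run(table, meta, seed=8)
        assert [r.mae for r in r1.fold_reports] == [r.mae for r in r2.fold_reports]
        assert r1.fold_selected == r2.fold_selected

    def test_no_test_fold_label_leak(self, cohort_small):
        """Poisoning the ages of fold 0's held-out samples must not change
        what fold 0 selects (its selection sees only training labels)."""
        from sklearn.model_selection import KFold

        table, meta = cohort_small
        baseline = self._run(table, meta, seed=8)
        te0 = list(KFold(3, shuffle=True, random_state=8).split(
            np.zeros((table.n_samples, 1))
        ))[0][1]
        poisoned = [
            SampleMetadata(m.sample_id, 7 if i in set(te0.tolist()) else m.age, m.sex)
            for i, m in enumerate(meta)
        ]
        out = self._run(table, poisoned, seed=8)
        assert out.fold_selected[0] == baseline.fold_selected[0]

    def test_too_few_folds_rejected(self, cohort_small):
        table, meta = cohort_small
        with pytest.raises(ValueError, match="folds"):
            self._run(table, meta, folds=1)
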
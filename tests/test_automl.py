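"""Bayesian optimizer, CV objective, metrics and evaluation protocols."""

import numpy as np
import pytest
from sklearn.dummy import DummyClassifier

import eegms
from conftest import two_gaussian_table
from eegms.automl import (
    bayes_optimize,
    classification_metrics,
    cv_objective,
    evaluate_holdout,
    expected_improvement,
    incremental_feature_curve,
    leave_one_subject_out,
)
from eegms.learners import SearchSpace, default_search_space

CHEAP = default_search_space().subset(["linear", "tree", "naive_bayes"])


class TestExpectedImprovement:
    def test_closed_form_cases(self):
        assert expected_improvement(np.array([0.5]), np.array([0.0]), 0.5)[0] == 0.0
        assert expected_improvement(np.array([0.4]), np.array([0.0]), 0.5)[0] == pytest.approx(0.1)
        ei = expected_improvement(np.array([0.5]), np.array([1.0]), 0.5)[0]
        assert ei == pytest.approx(1.0 / np.sqrt(2 * np.pi), abs=1e-12)

    def test_nonnegative_and_monotone_in_sd(self):
        sds = np.array([0.0, 0.1, 0.5, 2.0])
        ei = expected_improvement(np.full(4, 0.6), sds, 0.5)
        assert np.all(ei >= 0)
        assert np.all(np.diff(ei) > 0)  # worse mean, more sd -> more hope

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            expected_improvement(np.array([0.0]), np.array([-1.0]), 0.0)


class TestCVObjective:
    def test_separable_blobs_low_error(self):
        df = two_gaussian_table(n_per_class=60, d=4, sep=4.0, seed=0)
        x = df[[f"f{i}" for i in range(4)]].to_numpy()
        y = (df.group == "SZ").to_numpy().astype(int)
        est = CHEAP.build("linear", {"C": 1.0})
        assert cv_objective(est, x, y, k=5, seed=0) <= 0.05

    def test_majority_learner_on_balanced_data(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(100, 3))
        y = np.array([0, 1] * 50)
        assert cv_objective(DummyClassifier(strategy="prior"), x, y, 5, 0) == pytest.approx(0.5)

    def test_deterministic(self):
        df = two_gaussian_table(seed=2)
        x = df[[f"f{i}" for i in range(6)]].to_numpy()
        y = (df.group == "SZ").to_numpy().astype(int)
        est = CHEAP.build("tree", {"min_samples_leaf": 4})
        assert cv_objective(est, x, y, 5, 3) == cv_objective(est, x, y, 5, 3)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            cv_objective(DummyClassifier(), np.zeros((10, 2)), np.zeros(10))


def quadratic_space():
    """1-D continuous stub domain for optimizer-only tests."""
    return SearchSpace({"stub": {"x": ("float", -1.0, 2.0)}})


def quadratic_objective(learner, params):
    return (params["x"] - 0.3) ** 2


class TestBayesOptimize:
    def test_budget_one_returns_single_random_point(self):
        trace, model = bayes_optimize(
            quadratic_space(), objective=quadratic_objective, budget=1, seed=0
        )
        assert len(trace.values) == 1
        assert trace.incumbent_value == trace.values[0]
        assert model is None  # no data to refit on

    @pytest.mark.parametrize("seed", range(10))
    def test_quadratic_stub_close_to_grid_minimum(self, seed):
        """Dense-grid oracle: best found within 0.05 of the minimum over
        the domain at budget 30, for every seed."""
        grid = np.linspace(-1.0, 2.0, 20001)
        grid_min = ((grid - 0.3) ** 2).min()
        trace, _ = bayes_optimize(
            quadratic_space(), objective=quadratic_objective, budget=30, seed=seed
        )
        assert trace.incumbent_value - grid_min <= 0.05

    def test_incumbent_nonincreasing(self):
        trace, _ = bayes_optimize(
            quadratic_space(), objective=quadratic_objective, budget=25, seed=1
        )
        assert np.all(np.diff(trace.running_incumbent()) <= 0)

    @pytest.mark.parametrize("seed", range(5))
    def test_not_worse_than_random_search(self, seed):
        """With the deterministic stub, EI refinement of the shared random
        initial design is at least as good as pure random search."""
        space = quadratic_space()
        trace, _ = bayes_optimize(
            space, objective=quadratic_objective, budget=30, seed=seed
        )
        rng = np.random.default_rng(seed)
        rand_vals = [
            quadratic_objective("stub", space.sample("stub", rng))
            for _ in range(30)
        ]
        assert trace.incumbent_value <= min(rand_vals) + 1e-9

    def test_deterministic_given_seed(self):
        t1, _ = bayes_optimize(quadratic_space(), objective=quadratic_objective, budget=15, seed=5)
        t2, _ = bayes_optimize(quadratic_space(), objective=quadratic_objective, budget=15, seed=5)
        assert t1.values == t2.values
        assert t1.configs == t2.configs

    def test_all_failures_raise(self):
        def bad(learner, params):
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError, match="failed"):
            bayes_optimize(quadratic_space(), objective=bad, budget=3, seed=0)


class TestClassificationMetrics:
    def test_confusion_hand_case(self):
        """TP=9, FN=1, TN=8, FP=2 -> accuracy 85%, sens 90%, spec 80%."""
        y_true = np.array([1] * 10 + [0] * 10)
        y_pred = np.array([1] * 9 + [0] + [0] * 8 + [1] * 2)
        rep = classification_metrics(y_true, y_pred)
        assert rep.accuracy == pytest.approx(85.0)
        assert rep.sensitivity == pytest.approx(90.0)
        assert rep.specificity == pytest.approx(80.0)
        assert rep.confusion == {"tp": 9, "fn": 1, "tn": 8, "fp": 2}
        assert sum(rep.confusion.values()) == 20

    def test_perfect_and_reversed_scorer_auc(self):
        y = np.array([0, 0, 1, 1, 0, 1])
        scores = y.astype(float) * 2 - 1
        assert classification_metrics(y, y, scores).auc == 1.0
        assert classification_metrics(y, y, -scores).auc == 0.0

    def test_auc_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 50)
        s = rng.normal(size=50) + y
        a1 = classification_metrics(y, y, s).auc
        a2 = classification_metrics(y, y, np.exp(3 * s)).auc
        assert a1 == pytest.approx(a2)


class TestEvaluateHoldout:
    def test_separable_cohort_high_accuracy(self):
        """Full learner pool on a well-separated two-Gaussian cohort."""
        df = two_gaussian_table(n_per_class=100, d=4, sep=4.0, seed=4)
        rep = evaluate_holdout(df, budget=15, seed=0)
        assert rep.accuracy >= 95.0
        assert rep.auc >= 0.95
        assert rep.protocol == "subject_dependent"

    def test_deterministic_report(self):
        df = two_gaussian_table(n_per_class=40, d=3, sep=3.0, seed=5)
        r1 = evaluate_holdout(df, budget=6, space=CHEAP, seed=2)
        r2 = evaluate_holdout(df, budget=6, space=CHEAP, seed=2)
        assert r1.to_dict() == r2.to_dict()


class TestLeaveOneSubjectOut:
    def _table(self, n_subj=3, n_epochs=10, sep=4.0, seed=6):
        import pandas as pd

        rng = np.random.default_rng(seed)
        rows = []
        for g, off in (("HC", 0.0), ("SZ", sep)):
            for s in range(n_subj):
                for e in range(n_epochs):
                    rows.append({
                        "subject_id": f"{g}{s}", "group": g, "epoch": e,
                        "f0": rng.normal(off), "f1": rng.normal(off),
                    })
        return pd.DataFrame(rows)

    def test_fold_structure(self):
        table = self._table()
        avg, folds = leave_one_subject_out(table, budget=4, space=CHEAP, seed=0)
        assert len(folds) == 3  # min(n_HC, n_SZ) pairings
        for rep in folds:
            # each fold tests exactly the two held-out subjects' epochs
            assert sum(rep.confusion.values()) == 20
        assert sum(sum(r.confusion.values()) for r in folds) == 60
        assert avg.accuracy >= 90.0

    def test_too_few_subjects_rejected(self):
        table = self._table(n_subj=1)
        with pytest.raises(ValueError):
            leave_one_subject_out(table, space=CHEAP)


class TestIncrementalFeatureCurve:
    def test_curve_structure(self):
        df = two_gaussian_table(n_per_class=40, d=4, sep=3.0, seed=7)
        ranking = eegms.chi2_rank_features(df)
        reports = incremental_feature_curve(
            df, ranking, k_max=3, budget=4, space=CHEAP, seed=0
        )
        assert len(reports) == 3
        assert reports[0].features == [ranking.names[0]]
        assert reports[2].features == ranking.names[:3]

    def test_k_max_too_large_rejected(self):
        df = two_gaussian_table(n_per_class=20, d=3, seed=8)
        ranking = eegms.chi2_rank_features(df)
        with pytest.raises(ValueError):
            incremental_feature_curve(df, ranking, k_max=10, space=CHEAP)
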
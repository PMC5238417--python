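"""Discrete AdaBoost: the boosting loop, prediction, importance, evaluation."""

import warnings

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

import optimammo as om
from optimammo.classification import decision_scores


def best_stump_oracle(X, y, w):
    """Independent weighted-Gini stump search (midpoint thresholds)."""
    best = None
    for j in range(X.shape[1]):
        vals = np.unique(X[:, j])
        for thr in (vals[:-1] + vals[1:]) / 2.0:
            left = X[:, j] <= thr
            gini = 0.0
            labs = []
            for side in (left, ~left):
                ws = w[side].sum()
                if ws == 0:
                    labs.append(1)
                    continue
                p = w[side][y[side] == 1].sum() / ws
                gini += ws * 2.0 * p * (1.0 - p)
                labs.append(1 if p > 0.5 else -1)
            cand = (gini, j, thr, labs[0], labs[1])
            if best is None or cand[0] < best[0] - 1e-12:
                best = cand
    _, j, thr, ll, rl = best
    return np.where(X[:, j] <= thr, ll, rl)


def reference_boost_trace(X, y, n_rounds):
    """By-hand execution of the boosting loop with the stump oracle."""
    n = len(y)
    w = np.full(n, 1.0 / n)
    rows = []
    for _ in range(n_rounds):
        pred = best_stump_oracle(X, y, w)
        mis = pred != y
        err = float(w[mis].sum())
        c = float(np.log((1 - err) / err))
        rows.append({"weights_in": w.copy(), "err": err, "c": c, "pred": pred})
        w = w * np.where(mis, np.exp(c), 1.0)
        w = w / w.sum()
    return rows


# 8-point dataset with a unique optimal stump at every round
TRACE_X = np.arange(1.0, 9.0)[:, None]
TRACE_Y = np.array([-1, -1, -1, 1, 1, 1, -1, 1])


class TestBoostingLoop:
    def test_round_by_round_matches_hand_trace(self):
        """Weights, weighted errors and coefficients agree with an
        independent by-hand execution on the 8-point dataset (stumps, no
        bagging)."""
        n_rounds = 4
        model = om.train_discrete_adaboost(
            TRACE_X, TRACE_Y, n_rounds=n_rounds, base_depth=1,
            bagging_fraction=None, seed=0, keep_weight_history=True,
        )
        ref = reference_boost_trace(TRACE_X, TRACE_Y, n_rounds)
        for m in range(n_rounds):
            np.testing.assert_allclose(
                model.weight_history[m], ref[m]["weights_in"], rtol=1e-12
            )
            assert model.errors[m] == pytest.approx(ref[m]["err"], rel=1e-12)
            assert model.coefficients[m] == pytest.approx(ref[m]["c"], rel=1e-12)
            np.testing.assert_array_equal(
                model.trees[m].predict(TRACE_X), ref[m]["pred"]
            )

    def test_quarter_error_coefficient_is_ln_three(self):
        """A first-round stump erring on 2 of 8 uniform points has weighted
        error 1/4 and coefficient ln 3."""
        X = np.arange(1.0, 9.0)[:, None]
        y = np.array([-1, -1, -1, 1, 1, 1, -1, -1])
        model = om.train_discrete_adaboost(
            X, y, n_rounds=1, base_depth=1, bagging_fraction=None, seed=0
        )
        assert model.errors[0] == pytest.approx(0.25)
        assert model.coefficients[0] == pytest.approx(np.log(3.0))

    def test_separable_data_perfect_after_one_round(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(-1, 1, size=(60, 1))
        X = X[np.abs(X[:, 0]) > 0.05]
        y = np.where(X[:, 0] > 0, 1, -1)
        model = om.train_discrete_adaboost(
            X, y, n_rounds=1, base_depth=1, bagging_fraction=None, seed=0
        )
        pred, _ = om.predict(model, X)
        assert np.array_equal(pred, y)
        assert model.errors[0] == 0.0
        assert np.isfinite(model.coefficients[0])

    def test_weights_remain_probability_vector(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 4))
        y = np.where(X[:, 0] + 0.5 * rng.normal(size=50) > 0, 1, -1)
        model = om.train_discrete_adaboost(
            X, y, n_rounds=20, bagging_fraction=None, seed=3, keep_weight_history=True
        )
        for w in model.weight_history:
            assert w.min() >= 0
            assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_exponential_training_error_bound_holds(self):
        """The staged training error never exceeds prod_m 2 sqrt(e_m(1-e_m))."""
        rng = np.random.default_rng(4)
        X = rng.normal(size=(80, 3))
        y = np.where(X[:, 0] + 0.8 * rng.normal(size=80) > 0, 1, -1)
        model = om.train_discrete_adaboost(
            X, y, n_rounds=25, bagging_fraction=None, seed=5
        )
        scores = np.zeros(len(y))
        bound = 1.0
        for tree, c, err in zip(model.trees, model.coefficients, model.errors):
            scores += c * tree.predict(X)
            bound *= 2.0 * np.sqrt(max(err, 1e-12) * (1.0 - err))
            train_err = np.mean(np.where(scores > 0, 1, -1) != y)
            assert train_err <= bound + 1e-12

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValueError):
            om.train_discrete_adaboost(np.zeros((4, 1)), np.ones(4), seed=0)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(60, 5))
        y = np.where(X[:, 1] > 0, 1, -1)
        a = om.train_discrete_adaboost(X, y, n_rounds=15, seed=9)
        b = om.train_discrete_adaboost(X, y, n_rounds=15, seed=9)
        np.testing.assert_array_equal(a.coefficients, b.coefficients)
        np.testing.assert_array_equal(decision_scores(a, X), decision_scores(b, X))
        np.testing.assert_array_equal(
            om.variable_importance(a), om.variable_importance(b)
        )


class TestPrediction:
    def test_single_learner_prediction_equals_tree(self):
        model = om.train_discrete_adaboost(
            TRACE_X, TRACE_Y, n_rounds=1, base_depth=1, bagging_fraction=None, seed=0
        )
        pred, scores = om.predict(model, TRACE_X)
        np.testing.assert_array_equal(pred, model.trees[0].predict(TRACE_X))
        np.testing.assert_allclose(scores, model.coefficients[0] * model.trees[0].predict(TRACE_X))

    def test_negated_coefficients_flip_predictions(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(40, 2))
        y = np.where(X[:, 0] > 0, 1, -1)
        model = om.train_discrete_adaboost(X, y, n_rounds=7, seed=8)
        pred, scores = om.predict(model, X)
        assert np.all(scores != 0)
        flipped = om.BoostModel(
            trees=model.trees,
            coefficients=-model.coefficients,
            n_features=model.n_features,
        )
        pred2, _ = om.predict(flipped, X)
        np.testing.assert_array_equal(pred2, -pred)

    def test_tied_score_breaks_to_benign_with_flag(self):
        model = om.train_discrete_adaboost(
            TRACE_X, TRACE_Y, n_rounds=1, base_depth=1, bagging_fraction=None, seed=0
        )
        tied = om.BoostModel(
            trees=model.trees * 2,
            coefficients=np.array([1.0, -1.0]),
            n_features=1,
        )
        with pytest.warns(UserWarning, match="tied"):
            pred, scores = om.predict(tied, TRACE_X)
        assert np.all(scores == 0)
        assert np.all(pred == -1)

    def test_score_sweep_roc_matches_concordance_auc(self):
        """The threshold-sweep ROC area (scikit-learn) equals the pairwise
        concordance estimator."""
        rng = np.random.default_rng(9)
        X = rng.normal(size=(100, 3))
        y = np.where(X[:, 0] + rng.normal(size=100) > 0, 1, -1)
        model = om.train_discrete_adaboost(X, y, n_rounds=10, seed=10)
        scores = decision_scores(model, X)
        assert om.concordance_auc(scores, y) == pytest.approx(
            roc_auc_score(y, scores), abs=1e-12
        )


class TestVariableImportance:
    def test_unused_variable_scores_zero_and_sum_is_one(self):
        X = np.column_stack([TRACE_X[:, 0], np.zeros(8)])
        model = om.train_discrete_adaboost(
            X, TRACE_Y, n_rounds=3, base_depth=1, bagging_fraction=None, seed=0
        )
        imp = om.variable_importance(model)
        assert imp[1] == 0.0
        assert imp.sum() == pytest.approx(1.0, abs=1e-12)

    def test_informative_variable_ranks_first(self):
        """One informative + five noise variables: the informative one tops
        the ranking in >= 95% of seeded runs."""
        rng = np.random.default_rng(11)
        wins = 0
        runs = 100
        for i in range(runs):
            X = rng.normal(size=(120, 6))
            y = np.where(X[:, 2] + 0.5 * rng.normal(size=120) > 0, 1, -1)
            model = om.train_discrete_adaboost(X, y, n_rounds=10, base_depth=1, seed=i)
            imp = om.variable_importance(model)
            wins += np.argmax(imp) == 2
        assert wins >= 95


class TestEvaluation:
    def test_separable_cohort_is_perfectly_classified(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(120, 4))
        X = X[np.abs(X[:, 0]) > 0.05]
        y = np.where(X[:, 0] > 0, 1, -1)
        summary = om.evaluate_repeated(X, y, runs=5, n_rounds=10, seed=13)
        assert summary.misclassification_mean_sd[0] == pytest.approx(0.0, abs=1e-12)
        assert summary.sensitivity_mean_sd[0] == pytest.approx(100.0)
        assert summary.specificity_mean_sd[0] == pytest.approx(100.0)
        assert summary.auc == pytest.approx(1.0)

    def test_default_protocol_runs_twenty_times(self, paper_like_cohort):
        import inspect

        sig = inspect.signature(om.evaluate_repeated)
        assert sig.parameters["runs"].default == 20
        assert sig.parameters["n_rounds"].default == 50

    def test_evaluation_is_seed_reproducible(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(80, 5))
        y = np.where(X[:, 0] + rng.normal(size=80) > 0, 1, -1)
        a = om.evaluate_repeated(X, y, runs=4, n_rounds=10, seed=15)
        b = om.evaluate_repeated(X, y, runs=4, n_rounds=10, seed=15)
        np.testing.assert_array_equal(a.misclassification, b.misclassification)
        np.testing.assert_array_equal(a.importance_mean, b.importance_mean)
        assert a.auc == b.auc

    def test_oob_option_available(self):
        rng = np.random.default_rng(16)
        X = rng.normal(size=(90, 3))
        y = np.where(X[:, 0] > 0, 1, -1)
        summary = om.evaluate_repeated(X, y, runs=3, n_rounds=10, seed=17, method="oob")
        assert summary.runs == 3
        assert np.all(summary.misclassification >= 0)

    def test_importance_rank_orders_descending(self):
        rng = np.random.default_rng(18)
        X = rng.normal(size=(100, 4))
        y = np.where(X[:, 3] > 0, 1, -1)
        s = om.evaluate_repeated(X, y, runs=3, n_rounds=10, seed=19)
        rank = s.importance_rank()
        assert rank[0] == 3
        ordered = s.importance_mean[rank]
        assert np.all(np.diff(ordered) <= 1e-12)
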
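"""Discrete AdaBoost lesion classification with bagging and repeated runs.

The classifier combines M weak tree classifiers f_m(x) in {-1, +1} into
F(x) = sum_m c_m f_m(x), predicting sign(F).  The boosting loop:

    start with weights w_i = 1/N
    for m = 1..M:
        fit f_m with the current weights (through a weighted bootstrap
        sample when bagging is on)
        err_m = E_w[ 1(y != f_m(x)) ]          (weighted, full sample)
        c_m = log((1 - err_m) / err_m)         (no 1/2 factor)
        w_i *= exp(c_m) for misclassified i; renormalize to sum 1

Rounds with err_m = 0 keep a capped finite coefficient; rounds with
err_m >= 1/2 are discarded and resampled (both choices documented in the
methods note).  Variable importance is the c_m-weighted Gini impurity
decrease accumulated over all trees, normalized to sum 1.

Evaluation repeats training (default 20 times) and reports mean +/- SD
misclassification rate, sensitivity and specificity (malignant = positive
class) plus the pooled-score AUC, with out-of-bag prediction by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "BoostModel",
    "EvaluationSummary",
    "train_discrete_adaboost",
    "predict",
    "decision_scores",
    "variable_importance",
    "evaluate_repeated",
    "concordance_auc",
]

_C_CAP = 35.0  # coefficient cap for perfect rounds; exp(35) ~ 1.6e15
_MAX_RESAMPLE = 25


@dataclass
class BoostModel:
    """Trained Discrete AdaBoost ensemble."""

    trees: list
    coefficients: np.ndarray
    n_features: int
    feature_names: list | None = None
    seed: int | None = None
    errors: np.ndarray = field(default_factory=lambda: np.empty(0))
    oob_masks: np.ndarray | None = None  # (M, N) True where sample was out of bag
    weight_history: np.ndarray | None = None  # (M, N) weights entering each round

    @property
    def n_rounds(self) -> int:
        return len(self.trees)


def _check_xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or y.shape != (X.shape[0],):
        raise ValueError("X must be (n, d) with one label per row")
    classes = np.unique(y)
    if not np.array_equal(classes, [-1, 1]):
        raise ValueError("labels must be -1 (benign) and +1 (malignant), both present")
    return X, y.astype(int)


def train_discrete_adaboost(
    X,
    y,
    n_rounds: int = 50,
    base_depth: int = 2,
    bagging_fraction: float | None = 1.0,
    seed: int | None = None,
    feature_names=None,
    keep_weight_history: bool = False,
) -> BoostModel:
    """Train a Discrete AdaBoost ensemble of depth-limited trees.

    ``bagging_fraction`` sets the per-round bootstrap size as a fraction of
    N, drawn with replacement with probabilities proportional to the
    current weights; ``None`` disables bagging and fits each tree directly
    with the weights (the deterministic textbook loop).  The weighted
    error is always measured on the full sample.
    """
    X, y = _check_xy(X, y)
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    w = np.full(n, 1.0 / n)
    trees, coefs, errors = [], [], []
    oob_masks = []
    weight_history = [] if keep_weight_history else None
    m = 0
    attempts = 0
    while m < n_rounds:
        if keep_weight_history:
            weight_history.append(w.copy())
        tree = DecisionTreeClassifier(
            max_depth=base_depth,
            criterion="gini",
            random_state=int(rng.integers(2**31 - 1)),
        )
        if bagging_fraction is None:
            tree.fit(X, y, sample_weight=w)
            oob = np.zeros(n, dtype=bool)
        else:
            size = max(int(round(bagging_fraction * n)), 1)
            idx = rng.choice(n, size=size, replace=True, p=w)
            if np.unique(y[idx]).size < 2:
                attempts += 1
                if attempts > _MAX_RESAMPLE:
                    break
                if keep_weight_history:
                    weight_history.pop()
                continue
            tree.fit(X[idx], y[idx])
            oob = np.ones(n, dtype=bool)
            oob[idx] = False
        pred = tree.predict(X)
        mis = pred != y
        err = float(w[mis].sum())
        if err >= 0.5:
            # an anti-informative round: discard and draw a fresh sample
            attempts += 1
            if keep_weight_history:
                weight_history.pop()
            if bagging_fraction is None or attempts > _MAX_RESAMPLE:
                warnings.warn(
                    f"stopping at round {m}: weak learner error {err:.3f} >= 0.5",
                    stacklevel=2,
                )
                break
            continue
        attempts = 0
        c = _C_CAP if err <= 0.0 else min(float(np.log((1.0 - err) / err)), _C_CAP)
        w = w * np.where(mis, np.exp(c), 1.0)
        w = w / w.sum()
        trees.append(tree)
        coefs.append(c)
        errors.append(err)
        oob_masks.append(oob)
        m += 1
    names = list(feature_names) if feature_names is not None else None
    return BoostModel(
        trees=trees,
        coefficients=np.asarray(coefs),
        n_features=X.shape[1],
        feature_names=names,
        seed=seed,
        errors=np.asarray(errors),
        oob_masks=np.asarray(oob_masks) if oob_masks else None,
        weight_history=np.asarray(weight_history) if keep_weight_history else None,
    )


def decision_scores(model: BoostModel, X) -> np.ndarray:
    """Ensemble score F(x) = sum_m c_m f_m(x)."""
    X = np.asarray(X, dtype=float)
    scores = np.zeros(X.shape[0])
    for tree, c in zip(model.trees, model.coefficients):
        scores += c * tree.predict(X)
    return scores


def predict(model: BoostModel, X) -> tuple[np.ndarray, np.ndarray]:
    """Class prediction sign(F(x)) and the score F(x).

    Exact ties F(x) = 0 are broken to -1 (benign) and flagged with a
    warning.
    """
    scores = decision_scores(model, X)
    ties = scores == 0.0
    if ties.any():
        warnings.warn(
            f"{int(ties.sum())} tied ensemble score(s) broken to the benign class",
            stacklevel=2,
        )
    classes = np.where(scores > 0, 1, -1)
    return classes, scores


def variable_importance(model: BoostModel) -> np.ndarray:
    """Per-variable importance: c_m-weighted Gini impurity decrease.

    Summed over trees and splits, normalized to sum 1 (all-zero ensembles
    return zeros).  A variable never used in any split scores 0.
    """
    imp = np.zeros(model.n_features)
    for tree, c in zip(model.trees, model.coefficients):
        imp += c * tree.tree_.compute_feature_importances(normalize=False)
    total = imp.sum()
    return imp / total if total > 0 else imp


def concordance_auc(scores, y) -> float:
    """AUC as the pairwise concordance probability (ties get half credit).

    This is the Mann-Whitney U estimator of the area under the ROC curve,
    equivalent to integrating the ROC from a threshold sweep of the scores.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    pos = scores[y == 1]
    neg = scores[y == -1]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need both classes for AUC")
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    return float((gt + 0.5 * eq) / (pos.size * neg.size))


@dataclass
class EvaluationSummary:
    """Repeated-run evaluation: rates in %, AUC in [0, 1]."""

    misclassification: np.ndarray  # per-run %
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    importance_mean: np.ndarray  # mean normalized importance over runs
    runs: int
    seed: int | None

    @property
    def misclassification_mean_sd(self) -> tuple[float, float]:
        return float(self.misclassification.mean()), float(self.misclassification.std(ddof=1))

    @property
    def sensitivity_mean_sd(self) -> tuple[float, float]:
        return float(self.sensitivity.mean()), float(self.sensitivity.std(ddof=1))

    @property
    def specificity_mean_sd(self) -> tuple[float, float]:
        return float(self.specificity.mean()), float(self.specificity.std(ddof=1))

    def importance_rank(self) -> np.ndarray:
        """Variable indices ordered from most to least important."""
        return np.argsort(-self.importance_mean)


def _oob_scores(model: BoostModel, X) -> tuple[np.ndarray, np.ndarray]:
    """Out-of-bag ensemble score per sample (sum of c_m f_m over the rounds
    in which the sample was not drawn); second output marks samples with at
    least one out-of-bag round."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    scores = np.zeros(n)
    any_oob = np.zeros(n, dtype=bool)
    if model.oob_masks is None:
        raise ValueError("model was trained without bagging; no OOB information")
    for tree, c, oob in zip(model.trees, model.coefficients, model.oob_masks):
        pred = tree.predict(X)
        scores[oob] += c * pred[oob]
        any_oob |= oob
    return scores, any_oob


def evaluate_repeated(
    X,
    y,
    runs: int = 20,
    n_rounds: int = 50,
    base_depth: int = 2,
    bagging_fraction: float = 1.0,
    seed: int | None = None,
    method: str = "holdout",
    holdout_fraction: float = 0.3,
    feature_names=None,
) -> EvaluationSummary:
    """Repeat training and score the classifier.

    ``method="holdout"`` (default) retrains on a random split per run and
    evaluates the full ensemble on the held-out part.  ``method="oob"``
    scores each sample with the rounds that did not draw it; for a
    sequential booster those sub-ensembles lose the stagewise structure
    and systematically overstate the error, so OOB is offered for
    diagnostics, not as the headline estimate.  Reports per-run
    misclassification,
    sensitivity (malignant = positive) and specificity in percent, the
    pooled-score concordance AUC, and the run-averaged variable importance.
    """
    X, y = _check_xy(X, y)
    if runs < 2:
        raise ValueError("need at least 2 runs for mean +/- SD")
    ss = np.random.SeedSequence(seed)
    run_seeds = [int(s.generate_state(1)[0] & 0x7FFFFFFF) for s in ss.spawn(runs)]
    mis, sens, spec = [], [], []
    importances = []
    pooled_scores, pooled_y = [], []
    for r, rseed in enumerate(run_seeds):
        if method == "oob":
            model = train_discrete_adaboost(
                X, y, n_rounds, base_depth, bagging_fraction, rseed,
                feature_names=feature_names,
            )
            scores, valid = _oob_scores(model, X)
            y_eval = y[valid]
            s_eval = scores[valid]
        elif method == "holdout":
            rng = np.random.default_rng(rseed)
            n = X.shape[0]
            n_test = max(int(round(holdout_fraction * n)), 1)
            perm = rng.permutation(n)
            test, train = perm[:n_test], perm[n_test:]
            if np.unique(y[train]).size < 2 or np.unique(y[test]).size < 2:
                warnings.warn(f"run {r}: degenerate single-class split, skipped", stacklevel=2)
                continue
            model = train_discrete_adaboost(
                X[train], y[train], n_rounds, base_depth, bagging_fraction, rseed,
                feature_names=feature_names,
            )
            s_eval = decision_scores(model, X[test])
            y_eval = y[test]
        else:
            raise ValueError("method must be 'oob' or 'holdout'")
        if np.unique(y_eval).size < 2:
            warnings.warn(f"run {r}: evaluation set is single-class, skipped", stacklevel=2)
            continue
        pred = np.where(s_eval > 0, 1, -1)
        mis.append(100.0 * np.mean(pred != y_eval))
        sens.append(100.0 * np.mean(pred[y_eval == 1] == 1))
        spec.append(100.0 * np.mean(pred[y_eval == -1] == -1))
        importances.append(variable_importance(model))
        pooled_scores.append(s_eval)
        pooled_y.append(y_eval)
    if len(mis) < 2:
        raise ValueError("fewer than 2 usable evaluation runs")
    auc = concordance_auc(np.concatenate(pooled_scores), np.concatenate(pooled_y))
    return EvaluationSummary(
        misclassification=np.asarray(mis),
        sensitivity=np.asarray(sens),
        specificity=np.asarray(spec),
        auc=auc,
        importance_mean=np.mean(importances, axis=0),
        runs=len(mis),
        seed=seed,
    )
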
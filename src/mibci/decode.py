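"""Pairwise probabilistic decoding of imagery classes.

Three L2-regularized logistic regressions on CSP log-variance features form
the classifier bank driving the online controller:

* ``Y_EF`` — flexion vs. extension (output = p(flexion)),
* ``Y_OF`` — flexion vs. rest with the hand open (output = p(flexion)),
* ``Y_CE`` — extension vs. rest with the hand closed (output = p(extension)).

Training accuracies are estimated with five-fold block-wise (temporally
contiguous) cross-validation, refitting CSP inside every fold so no spatial
filter ever sees held-out data, and compared against a binomial chance level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.proportion import proportion_confint

from .sigproc import EpochSet, fit_csp, logvar_features, select_plausible_components

__all__ = [
    "PairwiseClassifier",
    "ClassifierBank",
    "train_pairwise",
    "train_bank",
    "blockwise_cv_accuracy",
    "binomial_chance_level",
    "accuracy_ci_above_chance",
    "CLASS_PAIRS",
]

#: Class pairings of the three classifiers (positive class first).
CLASS_PAIRS = {
    "Y_EF": ("flexion", "extension"),
    "Y_OF": ("flexion", "rest_open"),
    "Y_CE": ("extension", "rest_closed"),
}


class PairwiseClassifier(BaseEstimator, ClassifierMixin):
    """L2-penalized logistic regression on standardized features.

    Maximizes the L2-penalized binomial log-likelihood (penalty strength
    ``l2_lambda`` on the standardized coefficients, intercept unpenalized).
    ``predict_proba_pos`` returns p(positive class); ties at p = 0.5
    classify as the negative class.
    """

    def __init__(self, l2_lambda: float = 1.0, class_pair=None):
        self.l2_lambda = l2_lambda
        self.class_pair = class_pair

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if not np.all(np.isfinite(X)):
            raise ValueError("features must be finite")
        if self.l2_lambda <= 0:
            raise ValueError("l2_lambda must be positive")
        classes = list(self.class_pair) if self.class_pair is not None else sorted(set(y))
        if len(classes) != 2:
            raise ValueError(f"exactly two classes required, got {classes}")
        pos, neg = classes
        for c in (pos, neg):
            if np.sum(y == c) < 2:
                raise ValueError(f"need at least 2 samples of class {c!r}")
        self.positive_class_, self.negative_class_ = pos, neg

        self._scaler = StandardScaler().fit(X)
        Xs = self._scaler.transform(X)
        target = (y == pos).astype(int)
        self._lr = LogisticRegression(
            C=1.0 / self.l2_lambda, solver="lbfgs", tol=1e-10, max_iter=10_000,
        ).fit(Xs, target)
        # coefficients on the standardized feature scale
        self.weights_ = self._lr.coef_.ravel().copy()
        self.bias_ = float(self._lr.intercept_[0])
        return self

    def predict_proba_pos(self, X):
        check_is_fitted(self, "weights_")
        X = np.asarray(X, dtype=float)
        Xs = self._scaler.transform(X)
        idx = list(self._lr.classes_).index(1)
        return self._lr.predict_proba(Xs)[:, idx]

    def predict(self, X):
        p = self.predict_proba_pos(X)
        return np.where(p > 0.5, self.positive_class_, self.negative_class_)


def train_pairwise(features, labels, l2_lambda: float = 1.0,
                   class_pair=None) -> PairwiseClassifier:
    """Fit one pairwise probabilistic classifier on a feature matrix."""
    return PairwiseClassifier(l2_lambda=l2_lambda, class_pair=class_pair).fit(features, labels)


@dataclass
class ClassifierBank:
    """The three pairwise classifiers plus per-classifier decision thresholds."""

    classifiers: dict
    csp_models: dict
    thresholds: dict = field(default_factory=lambda: {"Y_EF": 0.7, "Y_OF": 0.7, "Y_CE": 0.7})

    def __post_init__(self):
        if set(self.classifiers) != set(CLASS_PAIRS):
            raise ValueError(f"bank must hold exactly {sorted(CLASS_PAIRS)}")
        for k, th in self.thresholds.items():
            if not 0.0 < th < 1.0:
                raise ValueError(f"threshold {k} must be in (0, 1), got {th}")


def train_bank(epochs: EpochSet, l2_lambda: float = 1.0, shrinkage: float = 0.0,
               plausibility_fraction: float = 0.5,
               select_plausible: bool = True) -> ClassifierBank:
    """Train the full bank from a labelled training :class:`EpochSet`.

    Per classifier: fit CSP on its class pair, optionally narrow the eight
    candidate filters to physiologically-plausible ones, extract
    log-variance features, and fit the logistic regression.
    """
    classifiers, csp_models = {}, {}
    for name, (pos, neg) in CLASS_PAIRS.items():
        pair = epochs.for_classes(pos, neg)
        model = fit_csp(pair.for_classes(pos), pair.for_classes(neg), shrinkage=shrinkage)
        if select_plausible:
            model = select_plausible_components(model, min_fraction=plausibility_fraction)
        feats = logvar_features(pair, model)
        classifiers[name] = train_pairwise(
            feats, pair.labels, l2_lambda=l2_lambda, class_pair=(pos, neg)
        )
        csp_models[name] = model
    return ClassifierBank(classifiers=classifiers, csp_models=csp_models)


def blockwise_cv_accuracy(epochs: EpochSet, class_pair, k: int = 5,
                          l2_lambda: float = 1.0, shrinkage: float = 0.0,
                          select_plausible: bool = True) -> float:
    """Five-fold block-wise cross-validated training accuracy.

    Trials of the two classes are kept in temporal order and split into
    ``k`` contiguous blocks; per fold, CSP and the classifier are fit on
    the training blocks only.  Contiguity means paired trials from one run
    never straddle folds, guarding against temporal leakage.
    """
    pos, neg = class_pair
    pair = epochs.for_classes(pos, neg)
    order = np.argsort(pair.onsets, kind="stable")
    pair = pair.subset(order)
    n_pos, n_neg = np.sum(pair.labels == pos), np.sum(pair.labels == neg)
    if k < 2:
        raise ValueError("k must be >= 2 (k=1 leaves no held-out data)")
    if k > min(n_pos, n_neg):
        raise ValueError(f"k={k} exceeds trials available per class ({n_pos}, {n_neg})")

    blocks = np.array_split(np.arange(pair.n_trials), k)
    accs = []
    for test_idx in blocks:
        train_mask = np.ones(pair.n_trials, dtype=bool)
        train_mask[test_idx] = False
        train, test = pair.subset(train_mask), pair.subset(~train_mask)
        if np.sum(train.labels == pos) < 2 or np.sum(train.labels == neg) < 2:
            raise ValueError("a fold left fewer than 2 training trials for a class")
        model = fit_csp(train.for_classes(pos), train.for_classes(neg), shrinkage=shrinkage)
        if select_plausible:
            model = select_plausible_components(model)
        clf = train_pairwise(
            logvar_features(train, model), train.labels,
            l2_lambda=l2_lambda, class_pair=(pos, neg),
        )
        pred = clf.predict(logvar_features(test, model))
        accs.append(float(np.mean(pred == test.labels)))
    return float(np.mean(accs))


def binomial_chance_level(n_trials: int, n_classes: int = 2, alpha: float = 0.05) -> float:
    """Minimum above-chance accuracy under a binomial test.

    Returns k*/n where k* is the smallest correct-trial count whose
    upper-tail probability under Binomial(n, 1/n_classes) is below alpha.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    k = np.arange(n_trials + 1)
    # P(X >= k) = sf(k - 1)
    upper_tail = stats.binom.sf(k - 1, n_trials, 1.0 / n_classes)
    k_star = int(k[np.argmax(upper_tail < alpha)])
    if upper_tail[k_star] >= alpha:  # even a perfect score cannot beat chance
        return 1.0
    return k_star / n_trials


def accuracy_ci_above_chance(accuracy: float, n_trials: int, alpha: float = 0.05,
                             n_classes: int = 2):
    """Wilson score interval for an accuracy; above chance iff its lower
    bound exceeds 1/n_classes."""
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    if not 0.0 <= accuracy <= 1.0:
        raise ValueError("accuracy must be in [0, 1]")
    count = int(round(accuracy * n_trials))
    lo, hi = proportion_confint(count, n_trials, alpha=alpha, method="wilson")
    return (float(lo), float(hi)), bool(lo > 1.0 / n_classes)
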
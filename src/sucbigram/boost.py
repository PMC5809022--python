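"""AdaBoost.M1 over decision stumps.

Discrete AdaBoost by reweighting, mirroring the classic Weka
AdaBoostM1-with-DecisionStump configuration: each round fits the stump
(one feature, one threshold, one class per side) minimizing weighted 0/1
error over all features and all midpoint thresholds between consecutive
distinct sorted values (plus a -inf threshold yielding a constant
classifier). A round with weighted error >= 1/2 is discarded and training
stops; a round with error 0 is kept and training stops. Retained rounds
get the classifier weight

    alpha_t = ln((1 - eps_t) / eps_t)

and misclassified samples have their weights multiplied by
(1 - eps_t)/eps_t before renormalization. Ties among equally good stumps
break toward the lower feature index, then the lower threshold, then
left_class 0, so training is fully deterministic.

The ensemble score is the alpha-weighted vote rescaled to [-1, 1]; label
1 is predicted iff the score is strictly positive.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

_EPS_ERR = 1e-12  # weighted errors below this count as exact separation


@dataclass(frozen=True)
class Stump:
    """One-level decision tree: predicts ``left_class`` where
    ``x[feature_index] <= threshold`` and ``right_class`` elsewhere."""

    feature_index: int
    threshold: float
    left_class: int
    right_class: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        left = X[:, self.feature_index] <= self.threshold
        return np.where(left, self.left_class, self.right_class)


def _best_stump(X: np.ndarray, y: np.ndarray, w: np.ndarray,
                order: np.ndarray, sv: np.ndarray) -> tuple[Stump, float]:
    """Vectorized stump search given presorted columns.

    ``order`` is the (n, d) per-column stable argsort of X and ``sv`` the
    sorted values. For a split of size k (left block = k smallest values)
    the (left=0, right=1) polarity errs on left positives and right
    negatives; the opposite polarity is its complement, so both errors
    come from one pair of weighted cumulative sums. Valid thresholds are
    midpoints between distinct consecutive values, plus -inf (constant
    stump). Tie-break: lower error, then lower feature index, then lower
    threshold, then left_class 0.
    """
    n, d = X.shape
    w_pos_total = float(w[y == 1].sum())
    w_neg_total = 1.0 - w_pos_total

    ws = w[order]
    ys = y[order]
    zeros = np.zeros((1, d))
    cum_p = np.vstack([zeros, np.cumsum(np.where(ys == 1, ws, 0.0), axis=0)])
    cum_n = np.vstack([zeros, np.cumsum(np.where(ys == 0, ws, 0.0), axis=0)])
    err01 = cum_p + (w_neg_total - cum_n)   # left_class=0, right_class=1
    err10 = 1.0 - err01

    invalid = np.ones((n + 1, d), dtype=bool)
    invalid[0] = False                       # k=0: threshold -inf
    if n > 1:
        invalid[1:n] = ~(sv[:-1] < sv[1:])   # midpoints need distinct values
    # k=n (all left) duplicates k=0 with swapped polarity; keep invalid
    err01 = np.where(invalid, np.inf, err01)
    err10 = np.where(invalid, np.inf, err10)

    # argmin along k returns the first (lowest-threshold) minimizer
    k01 = np.argmin(err01, axis=0)
    k10 = np.argmin(err10, axis=0)
    e01 = err01[k01, np.arange(d)]
    e10 = err10[k10, np.arange(d)]
    use10 = e10 < e01 - _EPS_ERR             # prefer polarity (0,1) on ties
    e_feat = np.where(use10, e10, e01)
    j = int(np.argmin(e_feat))               # first minimizer: lowest feature
    if use10[j]:
        k, lc, rc = int(k10[j]), 1, 0
    else:
        k, lc, rc = int(k01[j]), 0, 1
    thr = -np.inf if k == 0 else float((sv[k - 1, j] + sv[k, j]) / 2.0)
    return Stump(j, thr, lc, rc), max(float(e_feat[j]), 0.0)


def fit_stump(features, labels, sample_weights) -> tuple[Stump, float]:
    """Best decision stump under weighted 0/1 loss.

    Considers every feature, every midpoint threshold between consecutive
    distinct sorted values plus -inf (constant stump), and both side
    polarities; deterministic tie-breaking (see :func:`_best_stump`).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    w = np.asarray(sample_weights, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("features must be a 2-D matrix")
    n, d = X.shape
    if y.shape[0] != n or w.shape[0] != n:
        raise ValueError("labels/weights length mismatch")
    if not np.isclose(w.sum(), 1.0, atol=1e-8):
        raise ValueError("sample weights must sum to 1")
    order = np.argsort(X, axis=0, kind="stable")
    sv = np.take_along_axis(X, order, axis=0)
    return _best_stump(X, y, w, order, sv)


class StumpBoostClassifier(BaseEstimator, ClassifierMixin):
    """AdaBoost.M1 ensemble of decision stumps.

    Parameters
    ----------
    n_rounds : int
        Maximum boosting iterations (the reference configuration uses
        1000). Training may stop earlier on exact separation or on a
        round with weighted error >= 1/2.
    random_state : int or None
        Reserved for tie randomization; the default fitting procedure is
        fully deterministic and does not consume it.

    Attributes
    ----------
    stumps_ : list of :class:`Stump`
    alphas_ : ndarray of positive classifier weights, same length
    n_rounds_trained_ : int
    classes_ : ndarray ([0, 1])
    """

    def __init__(self, n_rounds: int = 1000, random_state: int | None = None):
        self.n_rounds = n_rounds
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if set(np.unique(y)) != {0, 1}:
            raise ValueError("both classes (0 and 1) must be present")
        n = X.shape[0]
        w = np.full(n, 1.0 / n)
        # presort once; only the weights change between rounds
        order = np.argsort(X, axis=0, kind="stable")
        sv = np.take_along_axis(X, order, axis=0)
        stumps: list[Stump] = []
        alphas: list[float] = []
        for _ in range(self.n_rounds):
            stump, eps = _best_stump(X, y, w, order, sv)
            if eps >= 0.5:
                break  # no better than chance: discard round, stop
            pred = stump.predict(X)
            if eps <= _EPS_ERR:
                # exact separation: keep with a large finite weight, stop
                stumps.append(stump)
                alphas.append(np.log((1.0 - _EPS_ERR) / _EPS_ERR))
                break
            alpha = float(np.log((1.0 - eps) / eps))
            stumps.append(stump)
            alphas.append(alpha)
            miss = pred != y
            w = w * np.where(miss, (1.0 - eps) / eps, 1.0)
            w /= w.sum()
        self.stumps_ = stumps
        self.alphas_ = np.asarray(alphas, dtype=float)
        self.n_rounds_trained_ = len(stumps)
        self.classes_ = np.array([0, 1])
        return self

    def decision_function(self, X) -> np.ndarray:
        """Normalized margin in [-1, 1]: the alpha-weighted average of the
        per-stump votes mapped to {-1, +1}."""
        check_is_fitted(self, "stumps_")
        if not self.stumps_:
            raise ValueError("ensemble is empty")
        X = np.asarray(X, dtype=float)
        votes = np.stack([2 * s.predict(X) - 1 for s in self.stumps_])
        return (self.alphas_ @ votes) / self.alphas_.sum()

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) > 0).astype(int)

    # -- plain-JSON serialization ------------------------------------

    def to_json(self) -> str:
        check_is_fitted(self, "stumps_")
        doc = [
            {"feature_index": s.feature_index,
             "threshold": s.threshold if np.isfinite(s.threshold) else "-inf",
             "left_class": s.left_class, "right_class": s.right_class,
             "alpha": float(a)}
            for s, a in zip(self.stumps_, self.alphas_)
        ]
        return json.dumps({"model": "stump-adaboost", "rounds": doc}, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "StumpBoostClassifier":
        doc = json.loads(text)
        clf = cls(n_rounds=len(doc["rounds"]))
        clf.stumps_ = [
            Stump(r["feature_index"],
                  -np.inf if r["threshold"] == "-inf" else float(r["threshold"]),
                  r["left_class"], r["right_class"])
            for r in doc["rounds"]
        ]
        clf.alphas_ = np.array([r["alpha"] for r in doc["rounds"]], dtype=float)
        clf.n_rounds_trained_ = len(clf.stumps_)
        clf.classes_ = np.array([0, 1])
        return clf

    def save(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path: str | os.PathLike) -> "StumpBoostClassifier":
        with open(path) as fh:
            return cls.from_json(fh.read())


def train_adaboost(features, labels, rounds: int = 1000,
                   seed: int | None = None) -> StumpBoostClassifier:
    """Functional wrapper: fit a :class:`StumpBoostClassifier`."""
    return StumpBoostClassifier(n_rounds=rounds, random_state=seed).fit(
        features, labels)


def predict_score(ensemble: StumpBoostClassifier, features) -> np.ndarray:
    """Normalized ensemble margin in [-1, 1]; label 1 iff score > 0."""
    return ensemble.decision_function(features)
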
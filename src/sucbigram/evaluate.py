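"""Chou-form classification metrics, ROC/AUC and cross-validation.

The four headline metrics are expressed through the class totals and the
per-class error counts: with N+ positives of which N-+ are missed, and N-
negatives of which N+- are miscalled,

    Sn  = 1 - N-+ / N+
    Sp  = 1 - N+- / N-
    Acc = 1 - (N-+ + N+-) / (N+ + N-)
    MCC = [1 - (N-+/N+ + N+-/N-)] /
          sqrt[(1 + (N+- - N-+)/N+) (1 + (N-+ - N+-)/N-)]

This MCC form is algebraically identical to the textbook
(TP*TN - FP*FN) / sqrt(...) expression. AUC is computed as the
Mann-Whitney rank statistic with ties contributing one half.

Cross-validation is stratified n-fold: train on n-1 folds, score the
held-out fold, average each metric over folds; AUC is reported from the
pooled out-of-fold scores (per-fold averaging is available as an option).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .boost import StumpBoostClassifier


@dataclass(frozen=True)
class ConfusionCounts:
    """Class totals and per-class error counts of a binary prediction."""

    n_pos: int   # N+  total positives
    n_neg: int   # N-  total negatives
    fn: int      # N-+ positives misclassified (missed sites)
    fp: int      # N+- negatives misclassified (false calls)

    def __post_init__(self) -> None:
        if not (0 <= self.fn <= self.n_pos):
            raise ValueError("fn must satisfy 0 <= fn <= n_pos")
        if not (0 <= self.fp <= self.n_neg):
            raise ValueError("fp must satisfy 0 <= fp <= n_neg")

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        return cls(
            n_pos=int((y_true == 1).sum()),
            n_neg=int((y_true == 0).sum()),
            fn=int(((y_true == 1) & (y_pred == 0)).sum()),
            fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        )


@dataclass
class MetricsReport:
    sensitivity: float
    specificity: float
    accuracy: float
    mcc: float
    auc: float | None = None
    mcc_undefined: bool = False
    per_fold: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def metrics(counts: ConfusionCounts) -> MetricsReport:
    """Sensitivity, specificity, accuracy and MCC from confusion counts."""
    n_pos, n_neg, fn, fp = counts.n_pos, counts.n_neg, counts.fn, counts.fp
    sens = 1.0 - fn / n_pos if n_pos else 0.0
    spec = 1.0 - fp / n_neg if n_neg else 0.0
    total = n_pos + n_neg
    acc = 1.0 - (fn + fp) / total if total else 0.0
    mcc_undefined = False
    if n_pos == 0 or n_neg == 0:
        mcc, mcc_undefined = 0.0, True
    else:
        num = 1.0 - (fn / n_pos + fp / n_neg)
        den_sq = (1.0 + (fp - fn) / n_pos) * (1.0 + (fn - fp) / n_neg)
        if den_sq <= 0:
            mcc, mcc_undefined = 0.0, True
        else:
            mcc = num / np.sqrt(den_sq)
    return MetricsReport(sensitivity=sens, specificity=spec, accuracy=acc,
                         mcc=mcc, mcc_undefined=mcc_undefined)


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve via the Mann-Whitney rank statistic;
    tied scores contribute one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    rank_sum_pos = ranks[labels == 1].sum()
    return float((rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def cross_validate(features, labels, n_folds: int, rounds: int = 1000,
                   seed: int = 0, pooled_auc: bool = True) -> MetricsReport:
    """Stratified n-fold cross-validation of the stump-boosting classifier.

    Per fold the four metrics are computed on the held-out fold; the
    report carries their across-fold averages. AUC comes from the pooled
    out-of-fold scores (set ``pooled_auc=False`` to average per-fold AUC
    instead).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    counts = np.bincount(y, minlength=2)
    if counts.min() < n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples, fewer than "
            f"{n_folds} folds; use fewer folds"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    per_fold: list[dict] = []
    oof_scores = np.empty(len(y))
    fold_aucs: list[float] = []
    for fold_no, (tr, te) in enumerate(skf.split(X, y)):
        if len(np.unique(y[tr])) < 2:
            raise ValueError(
                f"fold {fold_no}: training split lacks a class; "
                "use fewer folds"
            )
        clf = StumpBoostClassifier(n_rounds=rounds).fit(X[tr], y[tr])
        scores = clf.decision_function(X[te])
        oof_scores[te] = scores
        rep = metrics(ConfusionCounts.from_predictions(
            y[te], (scores > 0).astype(int)))
        fold_auc = roc_auc(scores, y[te]) if len(np.unique(y[te])) == 2 else None
        if fold_auc is not None:
            fold_aucs.append(fold_auc)
        per_fold.append({
            "fold": fold_no, "n_test": int(len(te)),
            "sensitivity": rep.sensitivity, "specificity": rep.specificity,
            "accuracy": rep.accuracy, "mcc": rep.mcc, "auc": fold_auc,
        })
    avg = {m: float(np.mean([f[m] for f in per_fold]))
           for m in ("sensitivity", "specificity", "accuracy", "mcc")}
    auc = (roc_auc(oof_scores, y) if pooled_auc
           else float(np.mean(fold_aucs)))
    return MetricsReport(**avg, auc=auc, per_fold=per_fold)


def random_negative_repeats(features_neg, features_pos, n_sets: int = 100,
                            set_size: int | None = None, *, n_folds: int = 10,
                            rounds: int = 1000, seed: int = 0,
                            ) -> tuple[list[MetricsReport], dict]:
    """Robustness to the choice of negative set: repeatedly draw a random
    negative subsample (without replacement), cross-validate against all
    positives, and summarize the spread of each metric.

    Returns the per-repeat reports and a ``{metric: (mean, sd)}`` summary.
    """
    Xn = np.asarray(features_neg, dtype=float)
    Xp = np.asarray(features_pos, dtype=float)
    if set_size is None:
        set_size = Xp.shape[0]
    if set_size > Xn.shape[0]:
        raise ValueError(
            f"set_size {set_size} exceeds available negatives {Xn.shape[0]}"
        )
    rng = np.random.default_rng(seed)
    reports: list[MetricsReport] = []
    for _ in range(n_sets):
        pick = rng.choice(Xn.shape[0], size=set_size, replace=False)
        X = np.vstack([Xp, Xn[pick]])
        y = np.concatenate([np.ones(Xp.shape[0], dtype=int),
                            np.zeros(set_size, dtype=int)])
        # the CV fold seed is held fixed across repeats so that only the
        # negative-set draw varies between reports
        reports.append(cross_validate(
            X, y, n_folds=n_folds, rounds=rounds, seed=seed))
    summary = {
        m: (float(np.mean([getattr(r, m) for r in reports])),
            float(np.std([getattr(r, m) for r in reports])))
        for m in ("sensitivity", "specificity", "accuracy", "mcc", "auc")
    }
    return reports, summary
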
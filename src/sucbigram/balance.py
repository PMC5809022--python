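"""Class balancing by iterative k-nearest-neighbor undersampling.

The negative (non-succinylation) class outnumbers the positive class by
roughly 10:1, so negatives lying close to positives in feature space are
pruned: every remaining negative whose k nearest neighbors (Euclidean,
unscaled feature space, self excluded) contain at least one positive is
removed. If a pass leaves the classes unbalanced, k is escalated in
integer multiples of the base threshold (floor(#negatives / #positives))
and the pass repeated on the remaining points, until the negatives no
longer outnumber the positives.

Removal within a round is simultaneous (mark-then-sweep), distances are
recomputed on the surviving set each round, and distance ties are broken
toward the lower original row index, so the procedure is deterministic
and order-independent.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)


def base_threshold(n_negative: int, n_positive: int) -> int:
    """Base neighbor count: floor(#negatives / #positives), at least 1."""
    if n_positive < 1:
        raise ValueError("need at least one positive sample")
    if n_negative < 1:
        raise ValueError("need at least one negative sample")
    return max(1, n_negative // n_positive)


@dataclass
class BalanceResult:
    """Outcome of the undersampling run."""

    kept_indices: np.ndarray          # original row indices, ascending
    final_k: int                      # threshold at termination
    rounds: list[tuple[int, int]] = field(default_factory=list)  # (k, removed)
    balanced: bool = True             # False if max_rounds hit first


class KnnUndersampler(BaseEstimator):
    """Iterative k-NN undersampler of the negative class.

    Parameters
    ----------
    base_k : int or "auto"
        Neighbor count of the first round; rounds r = 1, 2, ... use
        ``r * base_k``. ``"auto"`` derives it from the class counts as
        floor(#negatives / #positives).
    max_rounds : int
        Escalation cap so pathological geometries terminate; if reached
        without balance the result is flagged (``balanced_ = False``).
    chunk_size : int
        Query rows per distance-matrix block (memory bound only).

    Attributes
    ----------
    kept_indices_ : ndarray
        Original row indices surviving undersampling (all positives plus
        the kept negatives), ascending.
    base_k_ : int
        Resolved base threshold.
    final_k_ : int
        Threshold in force when the loop stopped.
    rounds_ : list of (k, n_removed)
        Per-round log.
    balanced_ : bool
        Whether negatives <= positives at termination.
    """

    def __init__(self, base_k: int | str = "auto", max_rounds: int = 20,
                 chunk_size: int = 2048):
        self.base_k = base_k
        self.max_rounds = max_rounds
        self.chunk_size = chunk_size

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("X must be 2-D with at least 2 rows")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        n_pos = int((y == 1).sum())
        n_neg = int((y == 0).sum())
        if n_pos == 0 or n_neg == 0:
            raise ValueError("both classes must be present")

        if self.base_k == "auto":
            base_k = base_threshold(n_neg, n_pos)
        else:
            base_k = int(self.base_k)
            if base_k < 1:
                raise ValueError("base_k must be >= 1")
        self.base_k_ = base_k

        remaining = np.arange(X.shape[0])
        rounds: list[tuple[int, int]] = []
        k = base_k
        balanced = n_neg <= n_pos
        r = 0
        while not balanced and r < self.max_rounds:
            r += 1
            k = r * base_k
            k_eff = min(k, remaining.size - 1)
            if k_eff < k:
                msg = (f"round {r}: k={k} >= remaining set size "
                       f"{remaining.size}, clamped to {k_eff}")
                logger.warning(msg)
                warnings.warn(msg, stacklevel=2)
            doomed = self._mark_negatives(X, y, remaining, k_eff,
                                          self.chunk_size)
            rounds.append((k, int(doomed.sum())))
            remaining = remaining[~doomed]
            n_neg_left = int((y[remaining] == 0).sum())
            balanced = n_neg_left <= n_pos
            logger.info("balance round %d (k=%d): removed %d negatives, "
                        "%d remain vs %d positives",
                        r, k, int(doomed.sum()), n_neg_left, n_pos)

        self.kept_indices_ = remaining
        self.final_k_ = k
        self.rounds_ = rounds
        self.balanced_ = balanced
        return self

    @staticmethod
    def _mark_negatives(X: np.ndarray, y: np.ndarray,
                        remaining: np.ndarray, k: int,
                        chunk_size: int = 2048) -> np.ndarray:
        """Boolean mask over ``remaining``: negatives whose k nearest
        neighbors within the remaining set include a positive."""
        Xr = X[remaining]
        yr = y[remaining]
        m = remaining.size
        doomed = np.zeros(m, dtype=bool)
        neg_rows = np.flatnonzero(yr == 0)
        for start in range(0, neg_rows.size, chunk_size):
            block = neg_rows[start:start + chunk_size]
            D = cdist(Xr[block], Xr)
            D[np.arange(block.size), block] = np.inf  # exclude self
            # stable sort: ties in distance resolve to the lower remaining
            # position, i.e. the lower original index (remaining is sorted)
            order = np.argsort(D, axis=1, kind="stable")[:, :k]
            doomed[block] = (yr[order] == 1).any(axis=1)
        return doomed

    def fit_resample(self, X, y):
        """Fit and return the undersampled ``(X, y)``."""
        self.fit(X, y)
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        return X[self.kept_indices_], y[self.kept_indices_]


def knn_balance(features, labels, base_k: int | str = "auto",
                max_rounds: int = 20) -> BalanceResult:
    """Functional wrapper around :class:`KnnUndersampler`."""
    sampler = KnnUndersampler(base_k=base_k, max_rounds=max_rounds)
    sampler.fit(features, labels)
    return BalanceResult(
        kept_indices=sampler.kept_indices_,
        final_k=sampler.final_k_,
        rounds=sampler.rounds_,
        balanced=sampler.balanced_,
    )
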
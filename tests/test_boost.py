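"""Decision-stump fitting and AdaBoost.M1 training."""

import numpy as np
import pytest

from sucbigram.boost import (Stump, StumpBoostClassifier, fit_stump,
                             predict_score, train_adaboost)


def exhaustive_stump_error(X, y, w):
    """Brute force over every (feature, midpoint-or--inf threshold,
    polarity); returns the minimal weighted error."""
    n, d = X.shape
    best = np.inf
    for j in range(d):
        vals = np.unique(X[:, j])
        thresholds = [-np.inf] + [
            (a + b) / 2 for a, b in zip(vals[:-1], vals[1:])]
        for thr in thresholds:
            for lc in (0, 1):
                pred = np.where(X[:, j] <= thr, lc, 1 - lc)
                err = w[pred != y].sum()
                best = min(best, err)
    return best


class TestFitStump:
    def test_separable_pair(self):
        X = np.array([[0.0], [1.0]])
        y = np.array([0, 1])
        stump, err = fit_stump(X, y, np.array([0.5, 0.5]))
        assert err == 0
        assert stump.threshold == 0.5
        assert (stump.left_class, stump.right_class) == (0, 1)

    def test_weight_dominance_flips_stump(self):
        # the mislabeled point carries 0.99 of the weight, so the best
        # stump classifies it correctly at the cost of everything else
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([0, 0, 0, 1])
        w = np.array([0.99, 0.005, 0.004, 0.001])
        y_flipped = y.copy()
        y_flipped[0] = 1
        stump, err = fit_stump(X, y_flipped, w)
        assert stump.predict(X[[0]])[0] == 1
        assert err <= 0.01

    def test_single_class_degenerates_to_constant(self):
        X = np.array([[0.0], [1.0], [2.0]])
        y = np.ones(3, dtype=int)
        stump, err = fit_stump(X, y, np.full(3, 1 / 3))
        assert err == 0
        np.testing.assert_array_equal(stump.predict(X), y)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.random((30, 5))
        y = rng.integers(0, 2, size=30)
        if len(np.unique(y)) == 1:
            y[0] = 1 - y[0]
        w = rng.random(30)
        w /= w.sum()
        _, err = fit_stump(X, y, w)
        assert err == pytest.approx(exhaustive_stump_error(X, y, w),
                                    abs=1e-12)

    def test_tie_breaks_to_lower_feature(self, rng):
        # duplicated feature columns: the winning stump must use column 0
        col = rng.random((20, 1))
        X = np.hstack([col, col, col])
        y = (col[:, 0] > 0.5).astype(int)
        stump, _ = fit_stump(X, y, np.full(20, 1 / 20))
        assert stump.feature_index == 0


class TestTrainAdaboost:
    def test_separable_data_stops_after_one_round(self):
        X = np.array([[0.0], [0.2], [0.8], [1.0]])
        y = np.array([0, 0, 1, 1])
        clf = train_adaboost(X, y, rounds=100)
        assert clf.n_rounds_trained_ == 1
        np.testing.assert_array_equal(clf.predict(X), y)

    def test_interval_labels_need_an_ensemble(self):
        # an interval-labeled line (0,1,1,0) defeats any single stump
        # (best weighted error 1/4) but a weighted stump ensemble drives
        # training error to 0
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([0, 1, 1, 0])
        _, err1 = fit_stump(X, y, np.full(4, 0.25))
        assert err1 == pytest.approx(0.25)
        clf = train_adaboost(X, y, rounds=50)
        assert clf.n_rounds_trained_ >= 3
        np.testing.assert_array_equal(clf.predict(X), y)

    def test_symmetric_xor_stops_with_empty_ensemble(self):
        # for 2-D XOR every axis stump has weighted error exactly 1/2,
        # so the eps >= 1/2 stopping rule terminates before any round is
        # retained: stumps cannot begin to learn this geometry
        X = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
        y = np.array([0, 1, 1, 0])
        clf = StumpBoostClassifier(n_rounds=50).fit(X, y)
        assert clf.n_rounds_trained_ == 0

    def test_training_is_deterministic(self, rng):
        X = rng.random((40, 6))
        y = rng.integers(0, 2, size=40)
        y[:2] = [0, 1]
        a = train_adaboost(X, y, rounds=30)
        b = train_adaboost(X, y, rounds=30)
        assert a.stumps_ == b.stumps_
        np.testing.assert_array_equal(a.alphas_, b.alphas_)

    def test_retained_rounds_beat_chance(self, rng):
        X = rng.random((60, 5))
        y = rng.integers(0, 2, size=60)
        y[:2] = [0, 1]
        clf = train_adaboost(X, y, rounds=50)
        assert np.all(clf.alphas_ > 0)  # alpha > 0 iff eps < 1/2

    def test_training_error_non_increasing_in_rounds(self, rng):
        from sucbigram.synthetic import planted_signal_features
        X, y = planted_signal_features(120, 0.5, seed=3)
        errs = []
        for rounds in (1, 10, 100):
            clf = train_adaboost(X, y, rounds=rounds)
            errs.append((clf.predict(X) != y).mean())
        assert errs == sorted(errs, reverse=True) or errs[-1] <= errs[0]

    def test_single_class_is_error(self):
        with pytest.raises(ValueError):
            train_adaboost(np.ones((5, 2)), np.ones(5, dtype=int))


class TestPredictScore:
    def test_single_stump_scores_are_plus_minus_one(self, rng):
        clf = StumpBoostClassifier(n_rounds=1).fit(
            np.array([[0.0], [1.0]]), np.array([0, 1]))
        scores = predict_score(clf, rng.random((20, 1)))
        assert set(np.unique(scores)) <= {-1.0, 1.0}

    def test_unanimous_vote_scores_one(self):
        clf = StumpBoostClassifier(n_rounds=5)
        clf.stumps_ = [Stump(0, 0.5, 0, 1)] * 3
        clf.alphas_ = np.array([1.0, 2.0, 0.5])
        clf.n_rounds_trained_ = 3
        clf.classes_ = np.array([0, 1])
        assert predict_score(clf, np.array([[2.0]]))[0] == 1.0

    def test_sign_matches_weighted_majority_vote(self, rng):
        from sucbigram.synthetic import planted_signal_features
        X, y = planted_signal_features(100, 0.5, seed=9)
        clf = train_adaboost(X, y, rounds=20)
        Xq = rng.random((100, 409))
        scores = predict_score(clf, Xq)
        votes = np.zeros(100)
        for s, a in zip(clf.stumps_, clf.alphas_):
            votes += a * (2 * s.predict(Xq) - 1)
        np.testing.assert_array_equal(scores > 0, votes > 0)

    def test_empty_ensemble_is_error(self):
        clf = StumpBoostClassifier()
        clf.stumps_, clf.alphas_ = [], np.array([])
        clf.n_rounds_trained_ = 0
        clf.classes_ = np.array([0, 1])
        with pytest.raises(ValueError, match="empty"):
            clf.decision_function(np.ones((1, 1)))


class TestSerialization:
    def test_json_round_trip_preserves_predictions(self, tmp_path, rng):
        from sucbigram.synthetic import planted_signal_features
        X, y = planted_signal_features(80, 0.5, seed=4)
        clf = train_adaboost(X, y, rounds=15)
        path = tmp_path / "model.json"
        clf.save(path)
        clf2 = StumpBoostClassifier.load(path)
        np.testing.assert_array_equal(clf.decision_function(X),
                                      clf2.decision_function(X))


def test_comparable_to_sklearn_adaboost(rng):
    """Independent cross-check: on an easy planted-signal problem our
    boosted stumps and sklearn's AdaBoost both reach high accuracy."""
    from sklearn.ensemble import AdaBoostClassifier
    from sklearn.tree import DecisionTreeClassifier
    from sucbigram.synthetic import planted_signal_features
    X, y = planted_signal_features(200, 1.0, seed=21)
    split = 150
    ours = train_adaboost(X[:split], y[:split], rounds=50)
    theirs = AdaBoostClassifier(
        estimator=DecisionTreeClassifier(max_depth=1), n_estimators=50,
        random_state=0).fit(X[:split], y[:split])
    acc_ours = (ours.predict(X[split:]) == y[split:]).mean()
    acc_theirs = (theirs.predict(X[split:]) == y[split:]).mean()
    assert acc_ours >= 0.9
    assert abs(acc_ours - acc_theirs) <= 0.1
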
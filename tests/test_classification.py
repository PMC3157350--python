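"""Binarization, classifier bank contracts, cross-validation and the CI."""

import numpy as np
import pytest

import facetraits.classification as clf_mod
from facetraits.classification import (
    ClassifierSpec,
    GentleBoost,
    KNNClassifier,
    ParzenRSClassifier,
    binarize_scores,
    classifier_bank,
    confidence_interval,
    make_classifier,
    nfold_cv,
)


def brute_force_stump(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Exhaustive 1-D weighted-least-squares stump: best (threshold, left, right)."""
    best = None
    candidates = [-np.inf] + [
        0.5 * (a + b) for a, b in zip(sorted(x)[:-1], sorted(x)[1:]) if a < b
    ]
    for theta in candidates:
        left = x <= theta
        lv = np.average(y[left], weights=w[left]) if left.any() else 0.0
        rv = np.average(y[~left], weights=w[~left]) if (~left).any() else 0.0
        pred = np.where(left, lv, rv)
        err = np.sum(w * (y - pred) ** 2)
        if best is None or err < best[0] - 1e-12:
            best = (err, theta, lv, rv)
    return best[1:]


class TestBinarize:
    def test_quartile_cut_on_ranked_scores(self):
        scores = {f"s{v}": float(v) for v in range(1, 9)}
        bl = binarize_scores(scores, 0.25)
        assert {i for i, l in bl.labels.items() if l == 1} == {"s8", "s7"}
        assert {i for i, l in bl.labels.items() if l == -1} == {"s1", "s2"}
        assert len(bl.discarded) == 4

    def test_tied_scores_deterministic_and_balanced(self):
        scores = {f"s{i:02d}": 5.0 for i in range(10)}
        bl = binarize_scores(scores, 0.3)
        labels = bl.label_vector()
        assert (labels == 1).sum() == (labels == -1).sum() == 3
        again = binarize_scores(scores, 0.3)
        assert bl.labels == again.labels

    def test_half_fraction_discards_nothing(self):
        scores = {f"s{i}": float(i) for i in range(8)}
        bl = binarize_scores(scores, 0.5)
        assert bl.discarded == ()

    @pytest.mark.parametrize("fraction", [0.0, 0.6, -0.1])
    def test_invalid_fraction(self, fraction):
        with pytest.raises(ValueError):
            binarize_scores({"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0}, fraction)


class TestGentleBoost:
    def test_single_stump_separates_1d_data(self):
        x = np.array([[0.0], [1.0], [2.0], [5.0], [6.0], [7.0]])
        y = np.array([-1, -1, -1, 1, 1, 1])
        gb = GentleBoost(n_iter=1).fit(x, y)
        assert np.array_equal(gb.predict(x), y)

    def test_first_stump_matches_exhaustive_search(self, rng):
        x = rng.normal(size=(30, 1))
        y = np.where(x[:, 0] + 0.3 * rng.normal(size=30) > 0, 1, -1)
        if len(set(y)) < 2:
            y[0] = -y[0]
        gb = GentleBoost(n_iter=1).fit(x, y)
        j, theta, left, right = gb.stumps_[0]
        o_theta, o_left, o_right = brute_force_stump(
            x[:, 0], y.astype(float), np.full(len(y), 1.0 / len(y))
        )
        assert j == 0
        assert theta == pytest.approx(o_theta)
        assert left == pytest.approx(o_left)
        assert right == pytest.approx(o_right)

    def test_xor_not_separable_by_one_stump(self):
        x = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]] * 5)
        y = np.array([-1, 1, 1, -1] * 5)
        gb = GentleBoost(n_iter=1).fit(x, y)
        assert np.mean(gb.predict(x) == y) <= 0.75

    def test_exp_loss_nonincreasing(self, rng):
        x = rng.normal(size=(40, 5))
        y = np.where(x[:, 0] + x[:, 1] > 0, 1, -1)
        gb = GentleBoost(n_iter=30).fit(x, y)
        losses = np.array([1.0] + gb.train_exp_loss_)
        assert np.all(np.diff(losses) <= 1e-12)

    def test_rejects_bad_labels(self, rng):
        with pytest.raises(ValueError):
            GentleBoost(1).fit(rng.normal(size=(4, 2)), np.array([0, 1, 0, 1]))
        with pytest.raises(ValueError):
            GentleBoost(1).fit(rng.normal(size=(4, 2)), np.array([1, 1, 1, 1]))


class TestKNN:
    def test_majority_vote_and_confidence(self):
        # 4 of the 5 nearest neighbours are positive -> class, confidence 0.8
        x_train = np.array([[0.0], [0.1], [0.2], [0.3], [0.4], [9.0], [9.1], [9.2]])
        y_train = np.array([1, 1, 1, 1, -1, -1, -1, -1])
        knn = KNNClassifier(k=5).fit(x_train, y_train)
        probe = np.array([[0.05]])
        assert knn.predict(probe)[0] == 1
        assert knn.confidence(probe)[0] == pytest.approx(0.8)

    def test_matches_brute_force_scan(self, rng):
        x_train = rng.normal(size=(50, 20))
        y_train = np.where(rng.random(50) > 0.5, 1, -1)
        if len(set(y_train)) < 2:
            y_train[0] = -y_train[0]
        x_test = rng.normal(size=(50, 20))
        knn = KNNClassifier(k=5).fit(x_train, y_train)
        preds = knn.predict(x_test)
        for i, xt in enumerate(x_test):
            d = np.linalg.norm(x_train - xt, axis=1)
            nbrs = sorted(range(50), key=lambda t: (d[t], t))[:5]
            vote = 1 if sum(y_train[t] == 1 for t in nbrs) > 2 else -1
            assert preds[i] == vote

    def test_even_k_rejected(self):
        with pytest.raises(ValueError):
            KNNClassifier(k=4)


class TestParzenRS:
    def test_degenerate_ensemble_equals_plain_parzen(self, rng):
        """M=1, ρ=1 must reproduce an explicitly coded full-feature
        two-class Gaussian-kernel density classifier."""
        x_train = rng.normal(size=(20, 3))
        y_train = np.array([1] * 10 + [-1] * 10)
        x_train[:10] += 1.0
        x_test = rng.normal(size=(15, 3)) + 0.5
        model = ParzenRSClassifier(n_subspaces=1, subspace_fraction=1.0, seed=0)
        model.fit(x_train, y_train)
        preds = model.predict(x_test)

        d = 3
        for i, xt in enumerate(x_test):  # independent per-sample loop oracle
            log_dens = {}
            for c in (1, -1):
                data = x_train[y_train == c]
                n_c = len(data)
                sigma = np.maximum(data.std(axis=0, ddof=1), 1e-3)
                h = sigma * (4.0 / ((d + 2) * n_c)) ** (1.0 / (d + 4))
                contrib = [
                    np.exp(-0.5 * np.sum(((xt - row) / h) ** 2))
                    / (np.prod(h) * (2 * np.pi) ** (d / 2))
                    for row in data
                ]
                log_dens[c] = np.log(np.mean(contrib)) + np.log(n_c / len(y_train))
            expected = 1 if log_dens[1] >= log_dens[-1] else -1
            assert preds[i] == expected

    def test_confidence_is_vote_share(self, rng):
        x = np.vstack([rng.normal(size=(15, 4)) + 2, rng.normal(size=(15, 4)) - 2])
        y = np.array([1] * 15 + [-1] * 15)
        model = ParzenRSClassifier(n_subspaces=9, subspace_fraction=0.5, seed=1).fit(x, y)
        conf = model.confidence(x)
        assert np.all((conf * 9) % 1 < 1e-9)  # multiples of 1/M
        assert np.all((conf >= 0) & (conf <= 1))


class TestLabelSymmetry:
    @pytest.mark.parametrize("method", ["gentleboost", "svm_rbf", "tree", "knn", "parzen_rs"])
    def test_accuracy_invariant_under_label_swap(self, method, rng):
        x = rng.normal(size=(40, 6))
        y = np.where(x[:, 0] + 0.5 * rng.normal(size=40) > 0, 1, -1)
        if len(set(y)) < 2:
            y[0] = -y[0]
        x_test = rng.normal(size=(20, 6))
        y_test = np.where(x_test[:, 0] > 0, 1, -1)
        spec = ClassifierSpec(method, params={"n_iter": 10, "n_subspaces": 5}
                              if method in ("gentleboost", "parzen_rs") else {}, seed=3)
        p1, _ = classifier_bank(spec, (x, y), x_test)
        p2, _ = classifier_bank(spec, (x, -y), x_test)
        acc1 = np.mean(p1 == y_test)
        acc2 = np.mean(p2 == -y_test)
        assert acc1 == pytest.approx(acc2)


class TestNFoldCV:
    def test_constant_classifier_scores_fifty_on_stratified_folds(self, monkeypatch, rng):
        class Constant:
            def fit(self, x, y):
                return self

            def predict(self, x):
                return np.ones(len(x), int)

            def confidence(self, x):
                return np.ones(len(x))

        monkeypatch.setattr(clf_mod, "make_classifier", lambda spec, seed=None: Constant())
        x = rng.normal(size=(40, 3))
        y = np.array([1, -1] * 20)
        res = nfold_cv(x, y, ClassifierSpec("knn"), n_folds=10, seed=0)
        assert np.allclose(res.fold_accuracies, 50.0)
        assert res.mean_accuracy == pytest.approx(50.0)

    def test_separated_clusters_are_perfectly_classified(self, rng):
        x = np.vstack([rng.normal(scale=0.2, size=(20, 2)) + 5,
                       rng.normal(scale=0.2, size=(20, 2)) - 5])
        y = np.array([1] * 20 + [-1] * 20)
        res = nfold_cv(x, y, ClassifierSpec("knn"), n_folds=5, seed=0)
        assert res.mean_accuracy == pytest.approx(100.0)

    def test_fold_bookkeeping_and_reproducibility(self, rng):
        x = rng.normal(size=(30, 4))
        y = np.array([1, -1] * 15)
        a = nfold_cv(x, y, ClassifierSpec("knn"), n_folds=5, seed=42)
        b = nfold_cv(x, y, ClassifierSpec("knn"), n_folds=5, seed=42)
        assert np.array_equal(a.fold_assignment, b.fold_assignment)
        assert np.array_equal(a.predictions, b.predictions)
        assert np.all(a.fold_assignment >= 0)  # every sample tested exactly once
        counts = np.bincount(a.fold_assignment, minlength=5)
        assert counts.sum() == 30

    def test_too_many_folds_rejected(self, rng):
        x = rng.normal(size=(8, 2))
        y = np.array([1, 1, 1, 1, -1, -1, -1, -1])
        with pytest.raises(ValueError, match="class size"):
            nfold_cv(x, y, ClassifierSpec("knn"), n_folds=5, seed=0)


class TestConfidenceInterval:
    def test_zero_spread_gives_zero_width(self):
        assert confidence_interval([80.0, 80.0, 80.0]) == 0.0

    def test_printed_fold_vector_against_direct_computation(self):
        accs = [60.0, 70.0, 80.0, 90.0, 100.0]
        s = np.std(accs, ddof=1)
        assert s == pytest.approx(15.8114, abs=1e-4)
        hw = confidence_interval(accs, level=0.95, multiplier="t")
        assert hw == pytest.approx(2.776 * s / np.sqrt(5), abs=0.01)
        assert hw == pytest.approx(19.63, abs=0.01)

    def test_monotone_in_spread(self):
        narrow = confidence_interval([70, 75, 80])
        wide = confidence_interval([60, 75, 90])
        assert wide > narrow

    def test_z_multiplier_smaller_than_t(self):
        accs = [60.0, 70.0, 80.0]
        assert confidence_interval(accs, multiplier="z") < confidence_interval(accs, multiplier="t")

    def test_single_fold_rejected(self):
        with pytest.raises(ValueError):
            confidence_interval([80.0])


def test_make_classifier_validates_specs():
    with pytest.raises(ValueError):
        make_classifier(ClassifierSpec("mlp"))
    with pytest.raises(ValueError):
        make_classifier(ClassifierSpec("knn", params={"k": 4}))
    with pytest.raises(ValueError):
        make_classifier(ClassifierSpec("parzen_rs", params={"subspace_fraction": 1.5}))
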
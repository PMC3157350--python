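"""Trait binarization, the five-classifier bank, and N-fold cross-validation.

Continuous trait ratings are turned into a binary problem by ranking the
scores and keeping only the top and bottom fractions ("class" vs
"no class"); the middle of the ranking is discarded to reduce the effect of
mislabeled or borderline samples.

The bank contains five classification rules spanning the main families:

* ``gentleboost`` — additive boosting of weighted-least-squares regression
  stumps (authored here; see GentleBoost),
* ``svm_rbf``     — SVM with an RBF kernel, (C, γ) tuned by inner grid-search CV,
* ``tree``        — binary decision tree with cost-complexity pruning tuned
  on the training fold,
* ``knn``         — k-nearest neighbours (k = 5) by Euclidean majority vote,
* ``parzen_rs``   — Parzen-window (Gaussian kernel density) classifiers on
  random feature subspaces, combined by majority vote.

Every classifier exposes a real-valued confidence (margin, signed
probability, or vote share): larger means "more class-like", which is what
the gallery-ranking analysis consumes.

Accuracy is estimated with stratified N-fold cross-validation; per-feature
z-scoring is fitted on each training fold.  The mean fold accuracy is
reported with a confidence-interval half-width t·s/√N (s = sample SD of
the fold accuracies, N = number of folds; a z multiplier is available as a
configuration switch).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import logsumexp
from scipy.stats import norm as _norm
from scipy.stats import t as _student_t
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "METHODS",
    "BinaryTraitLabels",
    "ClassifierSpec",
    "CVResult",
    "binarize_scores",
    "GentleBoost",
    "train_gentleboost",
    "make_classifier",
    "classifier_bank",
    "nfold_cv",
    "confidence_interval",
]

METHODS = ("gentleboost", "svm_rbf", "tree", "knn", "parzen_rs")


# ---------------------------------------------------------------------------
# Binarization


@dataclass(frozen=True)
class BinaryTraitLabels:
    """Equal-sized high/low subsets of a ranked trait score list."""

    trait: str
    ids: tuple[str, ...]  # selected ids, ascending id order
    labels: dict[str, int]  # id -> +1 (class) / -1 (no_class)
    discarded: tuple[str, ...]
    fraction: float

    def label_vector(self) -> np.ndarray:
        return np.array([self.labels[i] for i in self.ids])


def binarize_scores(scores, fraction: float, trait: str = "") -> BinaryTraitLabels:
    """Top ``fraction`` of the ranking -> class (+1); bottom -> no_class (−1).

    ``scores`` maps sample id -> continuous rating.  Ties in the ranking are
    broken by ascending sample id (stable).  With an odd sample count and
    fraction 0.5 the per-side count is capped so the sets stay disjoint.
    """
    if not (0.0 < fraction <= 0.5):
        raise ValueError("fraction must be in (0, 0.5]")
    items = dict(scores)
    ids = sorted(items)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least two samples")
    n_side = min(math.ceil(fraction * n), n // 2)
    if n_side < 1:
        raise ValueError("fraction selects no samples")
    order = sorted(ids, key=lambda i: items[i])  # stable: id asc within ties
    low = set(order[:n_side])
    high = set(order[n - n_side :])
    labels = {}
    for i in ids:
        if i in high:
            labels[i] = 1
        elif i in low:
            labels[i] = -1
    selected = tuple(i for i in ids if i in labels)
    discarded = tuple(i for i in ids if i not in labels)
    return BinaryTraitLabels(
        trait=trait, ids=selected, labels=labels, discarded=discarded, fraction=fraction
    )


# ---------------------------------------------------------------------------
# GentleBoost with regression stumps


class NotFittedError(RuntimeError):
    pass


class GentleBoost:
    """Gentle boosting of weighted-least-squares regression stumps.

    Each round fits, over every (feature, threshold) pair, the stump
    f(x) = a·[x_j > θ] + b minimizing the weighted squared error to the ±1
    labels, adds it to the additive score F, and re-weights samples by
    exp(−y·f(x)).  Prediction is sign(F); F itself is the confidence
    margin.  ``train_exp_loss_`` records the mean exponential loss per
    round (non-increasing).
    """

    def __init__(self, n_iter: int = 100):
        if n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        self.n_iter = n_iter
        self.stumps_: list[tuple[int, float, float, float]] | None = None  # (j, θ, left, right)
        self.train_exp_loss_: list[float] = []

    def fit(self, x: np.ndarray, y: np.ndarray) -> "GentleBoost":
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        if set(np.unique(y)) - {-1.0, 1.0}:
            raise ValueError("labels must be coded ±1")
        if len(np.unique(y)) < 2:
            raise ValueError("training fold contains a single class")
        n, n_feat = x.shape
        order = np.argsort(x, axis=0, kind="stable")
        xs = np.take_along_axis(x, order, axis=0)
        valid = np.zeros((n, n_feat), bool)
        valid[0] = True  # split with empty left block == constant stump
        valid[1:] = xs[1:] > xs[:-1]

        w = np.full(n, 1.0 / n)
        f_total = np.zeros(n)
        self.stumps_ = []
        self.train_exp_loss_ = []
        for _ in range(self.n_iter):
            wy = w * y
            w_sorted = w[order]
            wy_sorted = wy[order]
            # prefix sums over the first i elements, i = 0..n-1
            sw_l = np.vstack([np.zeros(n_feat), np.cumsum(w_sorted, axis=0)[:-1]])
            swy_l = np.vstack([np.zeros(n_feat), np.cumsum(wy_sorted, axis=0)[:-1]])
            sw_r = w.sum() - sw_l
            swy_r = wy.sum() - swy_l
            with np.errstate(divide="ignore", invalid="ignore"):
                gain = np.where(sw_l > 0, swy_l**2 / sw_l, 0.0) + np.where(
                    sw_r > 0, swy_r**2 / sw_r, 0.0
                )
            gain[~valid] = -np.inf
            i, j = np.unravel_index(int(np.argmax(gain)), gain.shape)
            left = swy_l[i, j] / sw_l[i, j] if sw_l[i, j] > 0 else 0.0
            right = swy_r[i, j] / sw_r[i, j] if sw_r[i, j] > 0 else 0.0
            theta = -np.inf if i == 0 else 0.5 * (xs[i - 1, j] + xs[i, j])
            fx = np.where(x[:, j] > theta, right, left)
            self.stumps_.append((int(j), float(theta), float(left), float(right)))
            f_total += fx
            w = w * np.exp(-y * fx)
            self.train_exp_loss_.append(float(np.mean(np.exp(-y * f_total))))
            total = w.sum()
            if total <= 0 or not np.isfinite(total):
                break
            w /= total
        return self

    def decision_function(self, x: np.ndarray) -> np.ndarray:
        if self.stumps_ is None:
            raise NotFittedError("GentleBoost is not fitted")
        x = np.asarray(x, float)
        f = np.zeros(x.shape[0])
        for j, theta, left, right in self.stumps_:
            f += np.where(x[:, j] > theta, right, left)
        return f

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.where(self.decision_function(x) >= 0, 1, -1)

    confidence = decision_function


def train_gentleboost(features, labels, n_iter: int = 100) -> GentleBoost:
    return GentleBoost(n_iter=n_iter).fit(np.asarray(features, float), np.asarray(labels, float))


# ---------------------------------------------------------------------------
# Remaining bank members


class SVMRBFClassifier:
    """RBF-kernel SVM; (C, γ) picked by inner stratified grid-search CV."""

    def __init__(self, c_grid=(1.0, 10.0, 100.0), gamma_factors=(0.1, 1.0, 10.0),
                 inner_folds: int = 3, seed: int = 0):
        self.c_grid = tuple(c_grid)
        self.gamma_factors = tuple(gamma_factors)
        self.inner_folds = inner_folds
        self.seed = seed
        self.model_ = None

    def fit(self, x, y):
        x = np.asarray(x, float)
        y = np.asarray(y)
        var = x.var()
        g0 = 1.0 / (x.shape[1] * var) if var > 0 else 1.0
        grid = {"C": list(self.c_grid), "gamma": [g0 * f for f in self.gamma_factors]}
        inner = StratifiedKFold(self.inner_folds, shuffle=True, random_state=self.seed)
        search = GridSearchCV(SVC(kernel="rbf"), grid, cv=inner, n_jobs=1)
        search.fit(x, y)
        self.model_ = search.best_estimator_
        return self

    def predict(self, x):
        self._check()
        return self.model_.predict(np.asarray(x, float)).astype(int)

    def confidence(self, x):
        self._check()
        return self.model_.decision_function(np.asarray(x, float))

    def _check(self):
        if self.model_ is None:
            raise NotFittedError("SVMRBFClassifier is not fitted")


class PrunedTreeClassifier:
    """Impurity-split binary tree; cost-complexity α tuned by inner CV."""

    def __init__(self, inner_folds: int = 3, max_alphas: int = 8, seed: int = 0):
        self.inner_folds = inner_folds
        self.max_alphas = max_alphas
        self.seed = seed
        self.model_ = None

    def fit(self, x, y):
        x = np.asarray(x, float)
        y = np.asarray(y)
        path = DecisionTreeClassifier(random_state=self.seed).cost_complexity_pruning_path(x, y)
        alphas = np.unique(np.clip(path.ccp_alphas, 0.0, None))[:-1]  # drop root-only tree
        if alphas.size == 0:
            alphas = np.array([0.0])
        if alphas.size > self.max_alphas:
            idx = np.linspace(0, alphas.size - 1, self.max_alphas).round().astype(int)
            alphas = alphas[np.unique(idx)]
        best_alpha, best_score = float(alphas[0]), -np.inf
        inner = StratifiedKFold(self.inner_folds, shuffle=True, random_state=self.seed)
        for alpha in alphas:
            scores = []
            for tr, te in inner.split(x, y):
                m = DecisionTreeClassifier(random_state=self.seed, ccp_alpha=float(alpha))
                m.fit(x[tr], y[tr])
                scores.append(np.mean(m.predict(x[te]) == y[te]))
            score = float(np.mean(scores))
            if score > best_score:  # ties keep the smaller (less pruned) alpha
                best_alpha, best_score = float(alpha), score
        self.model_ = DecisionTreeClassifier(random_state=self.seed, ccp_alpha=best_alpha)
        self.model_.fit(x, y)
        return self

    def predict(self, x):
        self._check()
        return self.model_.predict(np.asarray(x, float)).astype(int)

    def confidence(self, x):
        self._check()
        proba = self.model_.predict_proba(np.asarray(x, float))
        pos = list(self.model_.classes_).index(1)
        return proba[:, pos] - proba[:, 1 - pos]

    def _check(self):
        if self.model_ is None:
            raise NotFittedError("PrunedTreeClassifier is not fitted")


class KNNClassifier:
    """k-nearest-neighbour majority vote with a fully specified contract:

    Euclidean distance; neighbour ties at equal distance broken by smaller
    training-sample index; confidence = share of the k neighbours voting
    for the positive class (0.8 when 4 of 5 neighbours are "class").
    """

    def __init__(self, k: int = 5):
        if k < 1 or k % 2 == 0:
            raise ValueError("k must be a positive odd integer")
        self.k = k
        self.x_ = None
        self.y_ = None

    def fit(self, x, y):
        self.x_ = np.asarray(x, float)
        self.y_ = np.asarray(y, int)
        if self.k > len(self.y_):
            raise ValueError("k exceeds the training-set size")
        return self

    def confidence(self, x):
        if self.x_ is None:
            raise NotFittedError("KNNClassifier is not fitted")
        x = np.asarray(x, float)
        if x.shape[1] != self.x_.shape[1]:
            raise ValueError("test feature dimension mismatch")
        d = cdist(x, self.x_)
        nbrs = np.argsort(d, axis=1, kind="stable")[:, : self.k]  # stable => index tie-break
        return (self.y_[nbrs] == 1).mean(axis=1)

    def predict(self, x):
        return np.where(self.confidence(x) > 0.5, 1, -1)


class ParzenRSClassifier:
    """Random-subspace ensemble of two-class Parzen-window classifiers.

    Each of M base classifiers sees a random fraction ρ of the features and
    compares Gaussian kernel-density estimates of the two classes
    (diagonal per-feature bandwidths by Silverman's rule, computed per
    class).  The ensemble decides by simple majority vote; confidence =
    share of subspaces voting for the positive class.  With M = 1 and
    ρ = 1 this reduces to a plain Parzen classifier on the full features.
    """

    def __init__(self, n_subspaces: int = 25, subspace_fraction: float = 0.5, seed: int = 0):
        if n_subspaces < 1:
            raise ValueError("n_subspaces must be >= 1")
        if not (0.0 < subspace_fraction <= 1.0):
            raise ValueError("subspace_fraction must be in (0, 1]")
        self.n_subspaces = n_subspaces
        self.subspace_fraction = subspace_fraction
        self.seed = seed
        self.subspaces_ = None

    def fit(self, x, y):
        x = np.asarray(x, float)
        y = np.asarray(y, int)
        rng = np.random.default_rng(self.seed)
        n_feat = x.shape[1]
        dim = max(1, round(self.subspace_fraction * n_feat))
        self.class_data_ = {c: x[y == c] for c in (-1, 1)}
        if any(len(v) == 0 for v in self.class_data_.values()):
            raise ValueError("both classes must be present in the training fold")
        self.log_priors_ = {c: np.log(len(v) / len(y)) for c, v in self.class_data_.items()}
        self.bandwidths_ = {}
        for c, data in self.class_data_.items():
            n_c = data.shape[0]
            sigma = np.maximum(data.std(axis=0, ddof=1) if n_c > 1 else np.ones(n_feat), 1e-3)
            factor = (4.0 / ((dim + 2) * n_c)) ** (1.0 / (dim + 4))
            self.bandwidths_[c] = sigma * factor
        self.subspaces_ = [
            np.sort(rng.choice(n_feat, size=dim, replace=False))
            for _ in range(self.n_subspaces)
        ]
        return self

    def _log_density(self, x, c, idx):
        data = self.class_data_[c][:, idx]
        h = self.bandwidths_[c][idx]
        diff = (x[:, None, idx] - data[None, :, :]) / h
        log_k = -0.5 * np.sum(diff**2, axis=2) - np.sum(np.log(h)) - 0.5 * len(idx) * np.log(2 * np.pi)
        return logsumexp(log_k, axis=1) - np.log(data.shape[0])

    def confidence(self, x):
        if self.subspaces_ is None:
            raise NotFittedError("ParzenRSClassifier is not fitted")
        x = np.asarray(x, float)
        votes = np.zeros(x.shape[0])
        for idx in self.subspaces_:
            score = (self._log_density(x, 1, idx) + self.log_priors_[1]) - (
                self._log_density(x, -1, idx) + self.log_priors_[-1]
            )
            votes += (score >= 0).astype(float)
        return votes / self.n_subspaces

    def predict(self, x):
        return np.where(self.confidence(x) > 0.5, 1, -1)


# ---------------------------------------------------------------------------
# Bank assembly and cross-validation


@dataclass(frozen=True)
class ClassifierSpec:
    method: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {METHODS}")
        k = self.params.get("k", 5)
        if self.method == "knn" and (k < 1 or k % 2 == 0):
            raise ValueError("knn k must be a positive odd integer")
        if self.method == "gentleboost" and self.params.get("n_iter", 100) < 1:
            raise ValueError("gentleboost n_iter must be >= 1")
        rho = self.params.get("subspace_fraction", 0.5)
        if self.method == "parzen_rs" and not (0.0 < rho <= 1.0):
            raise ValueError("parzen_rs subspace_fraction must be in (0, 1]")


def make_classifier(spec: ClassifierSpec, seed: int | None = None):
    spec.validate()
    seed = spec.seed if seed is None else seed
    p = spec.params
    if spec.method == "gentleboost":
        return GentleBoost(n_iter=p.get("n_iter", 100))
    if spec.method == "svm_rbf":
        return SVMRBFClassifier(
            c_grid=p.get("c_grid", (1.0, 10.0, 100.0)),
            gamma_factors=p.get("gamma_factors", (0.1, 1.0, 10.0)),
            inner_folds=p.get("inner_folds", 3),
            seed=seed,
        )
    if spec.method == "tree":
        return PrunedTreeClassifier(
            inner_folds=p.get("inner_folds", 3), max_alphas=p.get("max_alphas", 8), seed=seed
        )
    if spec.method == "knn":
        return KNNClassifier(k=p.get("k", 5))
    return ParzenRSClassifier(
        n_subspaces=p.get("n_subspaces", 25),
        subspace_fraction=p.get("subspace_fraction", 0.5),
        seed=seed,
    )


def classifier_bank(spec: ClassifierSpec, train, test):
    """Train one bank member and score a test set.

    ``train`` and ``test`` are (features, labels) / features; features are
    assumed already standardized with training-fold statistics (nfold_cv
    does this).  Returns (predicted ±1 labels, confidence scores).
    """
    x_train, y_train = train
    clf = make_classifier(spec)
    clf.fit(np.asarray(x_train, float), np.asarray(y_train))
    x_test = np.asarray(test, float)
    if x_test.shape[1] != np.asarray(x_train).shape[1]:
        raise ValueError("test feature dimension mismatch")
    return clf.predict(x_test), np.asarray(clf.confidence(x_test), float)


def confidence_interval(fold_accuracies, level: float = 0.95, multiplier: str = "t") -> float:
    """Half-width of the CI on the mean fold accuracy: mult · s / √N."""
    acc = np.asarray(fold_accuracies, float)
    n = acc.size
    if n < 2:
        raise ValueError("need at least two folds")
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    s = acc.std(ddof=1)
    if multiplier == "t":
        mult = _student_t.ppf(0.5 * (1 + level), n - 1)
    elif multiplier == "z":
        mult = _norm.ppf(0.5 * (1 + level))
    else:
        raise ValueError("multiplier must be 't' or 'z'")
    return float(mult * s / math.sqrt(n))


@dataclass
class CVResult:
    trait: str
    spec: ClassifierSpec
    fold_accuracies: np.ndarray  # percent
    mean_accuracy: float  # percent
    ci_half_width: float  # percent
    predictions: np.ndarray  # out-of-fold ±1, aligned with input order
    confidences: np.ndarray  # out-of-fold confidence scores
    fold_assignment: np.ndarray  # fold index per sample
    ids: tuple[str, ...] | None = None


class Standardizer:
    """Per-feature z-scoring fitted on the training fold."""

    def fit(self, x):
        x = np.asarray(x, float)
        self.mean_ = x.mean(axis=0)
        self.sd_ = np.maximum(x.std(axis=0), 1e-8)
        return self

    def transform(self, x):
        return (np.asarray(x, float) - self.mean_) / self.sd_


def nfold_cv(
    features,
    labels,
    spec: ClassifierSpec,
    n_folds: int = 10,
    seed: int = 0,
    *,
    level: float = 0.95,
    ci_multiplier: str = "t",
    featurizer=None,
    trait: str = "",
    ids=None,
) -> CVResult:
    """Stratified N-fold cross-validation of one bank member.

    ``features`` is either an (n, d) matrix, or — when ``featurizer`` is
    given — a sequence of raw per-sample objects; the featurizer is then
    refitted on each training fold (``featurizer.fit(items)`` /
    ``featurizer.transform(items)``), which keeps fold hygiene for
    descriptors that are themselves estimated from data (mean shape,
    eigen-basis, reference face).
    """
    y = np.asarray(labels, int)
    n = len(y)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    class_sizes = [int(np.sum(y == c)) for c in (-1, 1)]
    if min(class_sizes) == 0:
        raise ValueError("both classes must be present")
    if n_folds > min(class_sizes):
        raise ValueError(f"n_folds={n_folds} exceeds the smaller class size {min(class_sizes)}")

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_acc = np.zeros(n_folds)
    preds = np.zeros(n, int)
    confs = np.zeros(n)
    assignment = np.full(n, -1, int)
    matrix = None if featurizer is not None else np.asarray(features, float)

    for fold, (tr, te) in enumerate(skf.split(np.zeros(n), y)):
        if featurizer is not None:
            featurizer.fit([features[i] for i in tr])
            x_tr = np.asarray(featurizer.transform([features[i] for i in tr]), float)
            x_te = np.asarray(featurizer.transform([features[i] for i in te]), float)
        else:
            x_tr, x_te = matrix[tr], matrix[te]
        scaler = Standardizer().fit(x_tr)
        fold_seed = (spec.seed * 100003 + fold) % (2**31)
        clf = make_classifier(spec, seed=fold_seed)
        clf.fit(scaler.transform(x_tr), y[tr])
        x_te_s = scaler.transform(x_te)
        p = clf.predict(x_te_s)
        preds[te] = p
        confs[te] = clf.confidence(x_te_s)
        assignment[te] = fold
        fold_acc[fold] = 100.0 * float(np.mean(p == y[te]))

    return CVResult(
        trait=trait,
        spec=spec,
        fold_accuracies=fold_acc,
        mean_accuracy=float(fold_acc.mean()),
        ci_half_width=confidence_interval(fold_acc, level=level, multiplier=ci_multiplier),
        predictions=preds,
        confidences=confs,
        fold_assignment=assignment,
        ids=tuple(ids) if ids is not None else None,
    )
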
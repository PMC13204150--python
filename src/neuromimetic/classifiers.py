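"""Hybrid boosted classifiers and baselines.

All classifiers implement one contract — ``fit(X, y, rng=None)``,
``predict(X)`` returning {0,1} labels, ``predict_proba(X)`` returning an
(n, 2) row-stochastic table — so the evaluation grid is classifier-agnostic.

The zoo:

elm_adaboost
    AdaBoost.M1 over extreme learning machines (random frozen hidden layer,
    ridge-solved output weights), after min-max normalization of the inputs.
cart_adaboost
    AdaBoost.M1 over shallow CART trees (exact weighted-Gini splits).
hwblsa
    Real-valued (probability-based) boosting of weighted broad learning
    system base learners, with per-sample class-balance weights for
    imbalanced data.
soft_vote
    Equal-weight average of the class probabilities of logistic regression,
    a polynomial-kernel SVM, a random forest, and 5-nearest-neighbors.
rf, nbc, majority
    Standalone baselines (random forest, Gaussian naive Bayes, majority
    vote).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .data import ValidationError

log = logging.getLogger(__name__)


def _as_rng(rng) -> np.random.Generator:
    return rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)


def _sk_seed(rng) -> int:
    return int(_as_rng(rng).integers(2 ** 31 - 1))


# ---------------------------------------------------------------------------
# min-max normalization
# ---------------------------------------------------------------------------

class MinMaxNormalizer:
    """Per-column (x - min) / (max - min) with clipping for unseen values.

    Constant columns map to 0; transform of data beyond the training range is
    clipped to [0, 1].
    """

    def fit(self, X):
        X = np.asarray(X, dtype=float)
        self.min_ = X.min(axis=0)
        self.max_ = X.max(axis=0)
        span = self.max_ - self.min_
        self.span_ = np.where(span > 0, span, 1.0)
        self.constant_ = span == 0
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        Z = (X - self.min_) / self.span_
        Z[:, self.constant_] = 0.0
        return np.clip(Z, 0.0, 1.0)

    def fit_transform(self, X):
        return self.fit(X).transform(X)


def minmax_normalize_fit_apply(X):
    """Normalize and return (normalized table, fitted bounds)."""
    norm = MinMaxNormalizer()
    return norm.fit_transform(X), norm


# ---------------------------------------------------------------------------
# extreme learning machine
# ---------------------------------------------------------------------------

def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class ElmModel:
    """Single-hidden-layer network with random frozen input weights.

    Only the output weights beta are learned, by a ridge-regularized linear
    least-squares solve of the hidden-layer system H beta = T.
    """

    def __init__(self, n_hidden: int = 100, activation: str = "sigmoid",
                 ridge: float = 1e-6):
        if n_hidden < 1:
            raise ValidationError("hidden node count must be >= 1")
        self.n_hidden = n_hidden
        self.activation = activation
        self.ridge = ridge

    def _hidden(self, X):
        A = X @ self.W_ + self.t_
        if self.activation == "sigmoid":
            return _sigmoid(A)
        if self.activation == "tanh":
            return np.tanh(A)
        raise ValidationError(f"unknown activation '{self.activation}'")

    def fit(self, X, y, rng=None, sample_weight=None):
        rng = _as_rng(rng)
        X = np.asarray(X, dtype=float)
        targets = np.where(np.asarray(y) == 1, 1.0, -1.0)   # signed codes
        d = X.shape[1]
        self.W_ = rng.uniform(-1.0, 1.0, size=(d, self.n_hidden))
        self.t_ = rng.uniform(-1.0, 1.0, size=self.n_hidden)
        H = self._hidden(X)
        if self.ridge > 0:
            A = H.T @ H + self.ridge * np.eye(self.n_hidden)
            self.beta_ = np.linalg.solve(A, H.T @ targets)
        else:
            self.beta_, *_ = np.linalg.lstsq(H, targets, rcond=None)
        return self

    def decision_function(self, X):
        return self._hidden(np.asarray(X, dtype=float)) @ self.beta_

    def predict(self, X):
        return (self.decision_function(X) > 0).astype(int)

    def predict_proba(self, X):
        p1 = _sigmoid(self.decision_function(X))
        return np.column_stack([1 - p1, p1])


# ---------------------------------------------------------------------------
# AdaBoost.M1 over resampling base learners
# ---------------------------------------------------------------------------

class BoostedEnsemble:
    """Classic AdaBoost: weight-resampled bases, log-inverse-odds votes.

    Per round: base trained on a weight-resampled copy of the data;
    per-sample error e_t(i) = |f_t(p_i) - q_i| in {0, 1} with {0,1} class
    codes; proportional error eps_t = sum_i D_t(i) e_t(i); connection weight
    w_t = 0.5 * log(1/beta_t) with beta_t = eps_t / (1 - eps_t); weight
    update D_{t+1} ∝ D_t * beta_t^{1 - e_t}, renormalized to the simplex.
    Prediction thresholds the weighted vote at the class-code midpoint.
    """

    MAX_W = 0.5 * np.log(1e10)    # cap when a round has zero error

    def __init__(self, base_factory, n_rounds: int = 10, resample: bool = True):
        if n_rounds < 1:
            raise ValidationError("boosting rounds must be >= 1")
        self.base_factory = base_factory
        self.n_rounds = n_rounds
        self.resample = resample

    def fit(self, X, y, rng=None):
        rng = _as_rng(rng)
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        n = X.shape[0]
        D = np.full(n, 1.0 / n)         # uniform initial distribution
        self.models_ = []
        self.weights_ = []
        self.weight_history_ = []
        discarded = 0
        t = 0
        while t < self.n_rounds:
            self.weight_history_.append(D.copy())
            base = self.base_factory()
            if self.resample:
                idx = rng.choice(n, size=n, replace=True, p=D)
                base.fit(X[idx], y[idx], rng=rng)
            else:
                base.fit(X, y, rng=rng, sample_weight=D)
            pred = base.predict(X)
            e = np.abs(pred - y).clip(0, 1).astype(float)
            eps = float(D @ e)
            if eps == 0.0:
                self.models_.append(base)
                self.weights_.append(self.MAX_W)
                log.info("boosting round %d: zero error, stopping early", t)
                break
            if eps >= 0.5:
                discarded += 1
                log.info("boosting round %d: error %.3f >= 0.5, discarded", t, eps)
                D = np.full(n, 1.0 / n)
                t += 1
                if discarded >= self.n_rounds:
                    break
                continue
            beta = eps / (1.0 - eps)
            self.models_.append(base)
            self.weights_.append(0.5 * np.log(1.0 / beta))
            D = D * beta ** (1.0 - e)
            D = D / D.sum()
            t += 1
        if not self.models_:                 # every round discarded
            base = self.base_factory()
            base.fit(X, y, rng=rng)
            self.models_.append(base)
            self.weights_.append(1.0)
        self.weights_ = list(np.asarray(self.weights_, dtype=float))
        return self

    def vote_score(self, X):
        """Weighted mean of base predictions, in [0, 1]."""
        W = np.asarray(self.weights_)
        preds = np.stack([m.predict(X) for m in self.models_], axis=1)
        return preds @ W / W.sum()

    def predict(self, X):
        return (self.vote_score(X) > 0.5).astype(int)

    def predict_proba(self, X):
        s = self.vote_score(X)
        return np.column_stack([1 - s, s])


class ElmAdaboost:
    """Min-max normalization + AdaBoost over ELM base learners."""

    def __init__(self, n_rounds: int = 10, n_hidden: int = 100,
                 ridge: float = 1e-6, activation: str = "sigmoid",
                 resample: bool = True):
        self.n_rounds = n_rounds
        self.n_hidden = n_hidden
        self.ridge = ridge
        self.activation = activation
        self.resample = resample

    def fit(self, X, y, rng=None):
        rng = _as_rng(rng)
        self.norm_ = MinMaxNormalizer()
        Z = self.norm_.fit_transform(X)
        factory = lambda: ElmModel(self.n_hidden, self.activation, self.ridge)
        self.ensemble_ = BoostedEnsemble(factory, self.n_rounds,
                                         resample=self.resample)
        self.ensemble_.fit(Z, y, rng=rng)
        return self

    def predict(self, X):
        return self.ensemble_.predict(self.norm_.transform(X))

    def predict_proba(self, X):
        return self.ensemble_.predict_proba(self.norm_.transform(X))


# ---------------------------------------------------------------------------
# CART with exact weighted-Gini splits
# ---------------------------------------------------------------------------

def gini(labels, weights=None) -> float:
    """Gini impurity 1 - sum_c p_c^2 (weights fold into the proportions)."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValidationError("Gini impurity of an empty subset is undefined")
    if weights is None:
        weights = np.ones(labels.shape)
    total = weights.sum()
    p = np.array([weights[labels == c].sum() / total for c in np.unique(labels)])
    return float(1.0 - (p ** 2).sum())


def gini_gain(parent_labels, left_mask, weights=None) -> float:
    """Impurity decrease of a split: GI(S) - W_L GI(S_L) - W_R GI(S_R)."""
    labels = np.asarray(parent_labels)
    left_mask = np.asarray(left_mask, dtype=bool)
    if weights is None:
        weights = np.ones(labels.shape)
    if left_mask.all() or not left_mask.any():
        return 0.0
    wl = weights[left_mask].sum() / weights.sum()
    return float(gini(labels, weights)
                 - wl * gini(labels[left_mask], weights[left_mask])
                 - (1 - wl) * gini(labels[~left_mask], weights[~left_mask]))


class _Node:
    __slots__ = ("feature", "threshold", "left", "right", "prediction", "proba")

    def __init__(self):
        self.feature = None


class CartClassifier:
    """Binary CART with exhaustive threshold search maximizing weighted
    Gini gain; leaves predict the (weighted) majority class."""

    def __init__(self, max_depth: int = 3, min_leaf: int = 1):
        if max_depth < 1:
            raise ValidationError("max_depth must be >= 1")
        self.max_depth = max_depth
        self.min_leaf = min_leaf

    def _best_split(self, X, y, w):
        best = (None, None, 0.0)
        base = gini(y, w)
        total_w = w.sum()
        for j in range(X.shape[1]):
            order = np.argsort(X[:, j], kind="stable")
            xs, ys, ws = X[order, j], y[order], w[order]
            # cumulative class-1 weight left of each boundary
            w1 = np.cumsum(ws * ys)
            wt = np.cumsum(ws)
            boundary = np.flatnonzero(np.diff(xs) > 0)
            for b in boundary:
                nl = b + 1
                if nl < self.min_leaf or len(xs) - nl < self.min_leaf:
                    continue
                wl, wl1 = wt[b], w1[b]
                wr, wr1 = total_w - wl, w1[-1] - wl1
                gl = 1 - (wl1 / wl) ** 2 - (1 - wl1 / wl) ** 2
                gr = 1 - (wr1 / wr) ** 2 - (1 - wr1 / wr) ** 2
                gain = base - (wl / total_w) * gl - (wr / total_w) * gr
                if gain > best[2] + 1e-15:
                    thr = 0.5 * (xs[b] + xs[b + 1])
                    best = (j, thr, gain)
        return best

    def _grow(self, X, y, w, depth):
        node = _Node()
        w1 = w[y == 1].sum() / w.sum()
        node.proba = w1
        node.prediction = int(w1 > 0.5)
        if depth >= self.max_depth or len(np.unique(y)) == 1:
            return node
        j, thr, gain = self._best_split(X, y, w)
        if j is None or gain <= 0:
            return node
        left = X[:, j] <= thr
        node.feature, node.threshold = j, thr
        node.left = self._grow(X[left], y[left], w[left], depth + 1)
        node.right = self._grow(X[~left], y[~left], w[~left], depth + 1)
        return node

    def fit(self, X, y, rng=None, sample_weight=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        w = (np.ones(len(y)) if sample_weight is None
             else np.asarray(sample_weight, dtype=float))
        self.root_ = self._grow(X, y, w, 0)
        return self

    def _leaf(self, x):
        node = self.root_
        while node.feature is not None:
            node = node.left if x[node.feature] <= node.threshold else node.right
        return node

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return np.array([self._leaf(x).prediction for x in X], dtype=int)

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        p1 = np.array([self._leaf(x).proba for x in X])
        return np.column_stack([1 - p1, p1])


class CartAdaboost:
    """AdaBoost over shallow CART trees (weights folded into Gini)."""

    def __init__(self, n_rounds: int = 10, max_depth: int = 3, min_leaf: int = 1):
        self.n_rounds = n_rounds
        self.max_depth = max_depth
        self.min_leaf = min_leaf

    def fit(self, X, y, rng=None):
        factory = lambda: CartClassifier(self.max_depth, self.min_leaf)
        # CART takes the boosting distribution as sample weights directly
        self.ensemble_ = BoostedEnsemble(factory, self.n_rounds, resample=False)
        self.ensemble_.fit(X, y, rng=rng)
        return self

    def predict(self, X):
        return self.ensemble_.predict(X)

    def predict_proba(self, X):
        return self.ensemble_.predict_proba(X)


# ---------------------------------------------------------------------------
# weighted broad learning system
# ---------------------------------------------------------------------------

class WblsModel:
    """Weighted broad learning system.

    Linear random feature nodes J_i = X W_ei + b_ei (n windows), tanh
    enhancement nodes E_k = tanh(J^n W_ek + b_ek) (m nodes); the concatenated
    state U = [J^n | E^m] feeds a weighted ridge output layer

        W = (lambda I + U' V U)^{-1} U' V Q,

    where V = Z * M is diagonal: Z balances class sizes (majority-class
    samples get the constant eps in (0, 1]; minority-class samples get
    1/class_size) and M carries optional per-class misclassification costs
    (default all ones). Targets Q are one-hot.
    """

    def __init__(self, n_windows: int = 10, window_size: int = 10,
                 n_enhance: int = 100, lam: float = 2.0 ** -10,
                 eps: float = 0.5, class_costs=None):
        if not 0.0 < eps <= 1.0:
            raise ValidationError("eps must lie in (0, 1]")
        if lam <= 0:
            raise ValidationError("ridge parameter lambda must be positive")
        self.n_windows = n_windows
        self.window_size = window_size
        self.n_enhance = n_enhance
        self.lam = lam
        self.eps = eps
        self.class_costs = class_costs

    @staticmethod
    def balance_weights(y, eps: float) -> np.ndarray:
        """Per-sample class-balance weight Z_ii.

        Minority-class samples (class size <= mean class size) get 1/size, so
        each minority class carries unit total weight; majority-class samples
        get eps/size, shrinking the majority's total weight by the factor
        eps in (0, 1]. eps = 1 is classic balanced weighting; eps -> 0
        discards the majority, the limit of the exponential down-weighting
        this realizes stably.
        """
        y = np.asarray(y, dtype=int)
        classes, counts = np.unique(y, return_counts=True)
        mean_size = counts.mean()
        per_class = {c: (eps / cnt if cnt > mean_size else 1.0 / cnt)
                     for c, cnt in zip(classes, counts)}
        return np.array([per_class[c] for c in y])

    def _state(self, X):
        feats = [X @ W + b for W, b in zip(self.We_, self.be_)]
        Jn = np.hstack(feats)
        E = np.tanh(Jn @ self.Wk_ + self.bk_)
        return np.hstack([Jn, E])

    def fit(self, X, y, rng=None, sample_weight=None):
        rng = _as_rng(rng)
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        self.classes_ = np.unique(y)
        # standardize inputs so the tanh enhancement layer is in range
        self.mu_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.sd_ = np.where(sd > 0, sd, 1.0)
        Z = (X - self.mu_) / self.sd_
        d = Z.shape[1]
        self.We_ = [rng.uniform(-1, 1, size=(d, self.window_size))
                    for _ in range(self.n_windows)]
        self.be_ = [rng.uniform(-1, 1, size=self.window_size)
                    for _ in range(self.n_windows)]
        total_feat = self.n_windows * self.window_size
        self.Wk_ = rng.uniform(-1, 1, size=(total_feat, self.n_enhance))
        self.bk_ = rng.uniform(-1, 1, size=self.n_enhance)

        U = self._state(Z)
        n = U.shape[0]
        zw = self.balance_weights(y, self.eps)
        costs = np.ones(n)
        if self.class_costs is not None:
            costs = np.array([self.class_costs[c] for c in y], dtype=float)
        v = zw * costs
        if sample_weight is not None:
            v = v * np.asarray(sample_weight, dtype=float)
        self.v_ = v
        Q = np.zeros((n, len(self.classes_)))
        for k, c in enumerate(self.classes_):
            Q[y == c, k] = 1.0
        UtV = U.T * v
        k = U.shape[1]
        self.W_ = np.linalg.solve(self.lam * np.eye(k) + UtV @ U, UtV @ Q)
        return self

    def decision_scores(self, X):
        Z = (np.asarray(X, dtype=float) - self.mu_) / self.sd_
        return self._state(Z) @ self.W_

    def predict(self, X):
        return self.classes_[np.argmax(self.decision_scores(X), axis=1)]

    def predict_proba(self, X):
        S = self.decision_scores(X)
        S = S - S.max(axis=1, keepdims=True)
        P = np.exp(S)
        return P / P.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# HWBLSA: real-valued boosting of WBLS base learners
# ---------------------------------------------------------------------------

PROBA_FLOOR = 1e-10


def stage_scores(P: np.ndarray) -> np.ndarray:
    """Real-valued stage score h_l = (L-1) (log P_l - mean_l log P_l).

    Scores sum to zero across classes for every sample by construction.
    """
    L = P.shape[1]
    logP = np.log(np.clip(P, PROBA_FLOOR, None))
    return (L - 1) * (logP - logP.mean(axis=1, keepdims=True))


def round_weight(err: float, n_classes: int) -> float:
    """alpha_m = 0.5 ln((1-e)/e) + ln(L-1); at L=2 the classic AdaBoost alpha."""
    err = min(max(err, 1e-12), 1 - 1e-12)
    return 0.5 * np.log((1 - err) / err) + np.log(n_classes - 1)


class Hwblsa:
    """Boosting ensemble of WBLS base learners with probability-based
    stage scores and exponential-loss sample reweighting.

    Per round m: the base WBLS (fed the current sample weights through its
    diagonal weight matrix) yields class probabilities P^(m); stage scores
    h^(m) are the centered log-probabilities; sample weights update as
    w_i <- w_i * exp(-(L-1)/L * y_i' log P^(m)(x_i)) with symmetric simplex
    label codes y (1 for the true class, -1/(L-1) otherwise), then
    renormalize. Final label: argmax_l sum_m h_l^(m). Rounds with weighted
    error 0 or >= (L-1)/L stop the loop early.
    """

    def __init__(self, n_rounds: int = 10, **wbls_params):
        if n_rounds < 1:
            raise ValidationError("boosting rounds must be >= 1")
        self.n_rounds = n_rounds
        self.wbls_params = wbls_params

    def fit(self, X, y, rng=None):
        rng = _as_rng(rng)
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        n = X.shape[0]
        self.classes_ = np.unique(y)
        L = len(self.classes_)
        class_index = {c: k for k, c in enumerate(self.classes_)}
        yk = np.array([class_index[c] for c in y])
        codes = np.full((n, L), -1.0 / (L - 1))
        codes[np.arange(n), yk] = 1.0

        w = np.full(n, 1.0 / n)
        self.models_ = []
        self.alphas_ = []
        for m in range(self.n_rounds):
            base = WblsModel(**self.wbls_params)
            base.fit(X, y, rng=rng, sample_weight=w * n)
            P = np.clip(base.predict_proba(X), PROBA_FLOOR, None)
            pred = self.classes_[np.argmax(P, axis=1)]
            err = float(w @ (pred != y))
            self.models_.append(base)
            self.alphas_.append(round_weight(err, L))
            if err == 0.0 or err >= (L - 1) / L:
                log.info("hwblsa round %d: degenerate error %.3f, stopping", m, err)
                break
            logP = np.log(P)
            w = w * np.exp(-(L - 1) / L * (codes * logP).sum(axis=1))
            w = w / w.sum()
        return self

    def decision_scores(self, X):
        total = None
        for base in self.models_:
            P = base.predict_proba(X)
            h = stage_scores(P)
            total = h if total is None else total + h
        return total

    def predict(self, X):
        return self.classes_[np.argmax(self.decision_scores(X), axis=1)]

    def predict_proba(self, X):
        S = self.decision_scores(X)
        S = S - S.max(axis=1, keepdims=True)
        P = np.exp(S)
        return P / P.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# soft voting over standard machine-learning models
# ---------------------------------------------------------------------------

class SoftVoteEnsemble:
    """Equal-weight probability averaging of four standard models.

    Multinomial logistic regression (500-iteration cap), polynomial-kernel
    SVM with C=2 (probability-calibrated), a 250-tree random forest with
    depth cap 100, and 5-nearest-neighbors. A base model that fails to train
    or converge is excluded from the average with a logged warning.
    """

    def __init__(self, svm_C: float = 2.0, rf_estimators: int = 250,
                 rf_max_depth: int = 100, knn_k: int = 5, lr_max_iter: int = 500):
        self.svm_C = svm_C
        self.rf_estimators = rf_estimators
        self.rf_max_depth = rf_max_depth
        self.knn_k = knn_k
        self.lr_max_iter = lr_max_iter

    def _bases(self, rng):
        return {
            "lr": LogisticRegression(max_iter=self.lr_max_iter),
            "svm": CalibratedClassifierCV(
                SVC(kernel="poly", C=self.svm_C, random_state=_sk_seed(rng)),
                ensemble=False),
            "rf": RandomForestClassifier(n_estimators=self.rf_estimators,
                                         max_depth=self.rf_max_depth,
                                         random_state=_sk_seed(rng)),
            "knn": KNeighborsClassifier(n_neighbors=self.knn_k),
        }

    def fit(self, X, y, rng=None):
        rng = _as_rng(rng)
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        self.models_ = {}
        for name, model in self._bases(rng).items():
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("error", category=UserWarning)
                    model.fit(X, y)
            except Exception as exc:        # failed base: excluded, logged
                log.warning("soft-vote base '%s' excluded: %s", name, exc)
                continue
            self.models_[name] = model
        if not self.models_:
            raise ValidationError("every soft-vote base model failed to train")
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        probs = [m.predict_proba(X) for m in self.models_.values()]
        return np.mean(probs, axis=0)

    def predict(self, X):
        return np.argmax(self.predict_proba(X), axis=1)


# ---------------------------------------------------------------------------
# baselines and registry
# ---------------------------------------------------------------------------

class SkWrapper:
    """Adapter giving sklearn estimators the package's fit(X, y, rng) contract."""

    def __init__(self, factory):
        self._factory = factory

    def fit(self, X, y, rng=None):
        self.model_ = self._factory(_as_rng(rng))
        self.model_.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=int))
        return self

    def predict(self, X):
        return self.model_.predict(np.asarray(X, dtype=float))

    def predict_proba(self, X):
        return self.model_.predict_proba(np.asarray(X, dtype=float))


class MajorityClassifier:
    """Predicts the majority training class; harness baseline."""

    def fit(self, X, y, rng=None):
        y = np.asarray(y, dtype=int)
        self.majority_ = int(np.bincount(y, minlength=2).argmax())
        self.p1_ = float(np.mean(y == 1))
        return self

    def predict(self, X):
        return np.full(np.asarray(X).shape[0], self.majority_, dtype=int)

    def predict_proba(self, X):
        n = np.asarray(X).shape[0]
        return np.tile([1 - self.p1_, self.p1_], (n, 1))


CLASSIFIERS = {
    "elm_adaboost": ElmAdaboost,
    "cart_adaboost": CartAdaboost,
    "hwblsa": Hwblsa,
    "soft_vote": SoftVoteEnsemble,
    "rf": lambda **kw: SkWrapper(lambda rng: RandomForestClassifier(
        n_estimators=kw.get("n_estimators", 250),
        max_depth=kw.get("max_depth", 100), random_state=_sk_seed(rng))),
    "nbc": lambda **kw: SkWrapper(lambda rng: GaussianNB(**kw)),
    "elm": ElmModel,
    "cart": CartClassifier,
    "wbls": WblsModel,
    "majority": lambda **kw: MajorityClassifier(),
}


def make_classifier(name: str, **params):
    if name not in CLASSIFIERS:
        raise ValidationError(f"unknown classifier '{name}'")
    return CLASSIFIERS[name](**params)
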
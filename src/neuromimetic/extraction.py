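"""Train-then-transform feature extraction schemes.

Five reducers share one contract: ``fit(X, y=None, rng=None)`` estimates all
statistics from the training rows, ``transform(X)`` maps any table with the
training column count to exactly ``output_dim`` columns and never re-estimates
anything. Each scheme standardizes its input internally (per-column mean 0 /
variance 1, fitted on the training rows), so the extractors are insensitive to
per-feature units.

Schemes
-------
pca
    Projection onto the leading eigenvectors of the population covariance of
    standardized data.
kpls
    Kernel partial least squares (Gaussian kernel, double-centered Gram,
    NIPALS latent directions); supervised, so it uses the labels.
kriging
    Per-sample one-dimensional ordinary kriging: a sample's feature vector is
    read as observations of a random field at equispaced index locations in
    [0, 1] and interpolated onto ``output_dim`` target locations under a
    Gaussian covariance k(d) = sigma2 * exp(-d^2 / (2 l^2)).
isomap
    k-nearest-neighbor graph geodesics + classical scaling, with a Nystrom
    out-of-sample extension.
kmeans
    Lloyd clustering of the training rows; the transform emits the vector of
    Euclidean distances to the k centroids.
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components, shortest_path
from scipy.spatial.distance import cdist

from .data import ValidationError


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

def standardize_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column mean and population SD; constant columns get SD 1."""
    X = np.asarray(X, dtype=float)
    if X.size == 0 or X.shape[0] < 2:
        raise ValidationError("standardization needs at least 2 samples")
    mu = X.mean(axis=0)
    sigma = X.std(axis=0)          # population convention (ddof=0)
    sigma = np.where(sigma > 0, sigma, 1.0)
    return mu, sigma


def standardize_fit_transform(X: np.ndarray):
    """Standardize columns to mean 0 / variance 1; returns (table, mu, sigma)."""
    mu, sigma = standardize_fit(X)
    return (np.asarray(X, dtype=float) - mu) / sigma, mu, sigma


class _Standardized:
    """Mixin handling the internal standardization step."""

    def _fit_scaler(self, X):
        self.mu_, self.sigma_ = standardize_fit(X)
        return (X - self.mu_) / self.sigma_

    def _scale(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.mu_.shape[0]:
            raise ValidationError(
                f"expected {self.mu_.shape[0]} columns, got {X.shape[1]}")
        return (X - self.mu_) / self.sigma_


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

class PcaExtractor(_Standardized):
    """Eigen-projection of the population covariance of standardized data.

    Components are orthonormal eigenvectors ordered by descending eigenvalue;
    each eigenvector's sign is fixed by making its largest-magnitude loading
    positive, so fits are deterministic.
    """

    name = "pca"

    def __init__(self, output_dim: int = 10):
        self.output_dim = output_dim

    def fit(self, X, y=None, rng=None):
        Z = self._fit_scaler(np.asarray(X, dtype=float))
        n, p = Z.shape
        if not 1 <= self.output_dim <= min(n, p):
            raise ValidationError(
                f"output_dim={self.output_dim} must lie in [1, min(n,p)={min(n, p)}]")
        cov = (Z.T @ Z) / n
        eigvals, eigvecs = np.linalg.eigh(cov)
        order = np.argsort(eigvals)[::-1]
        eigvals, eigvecs = eigvals[order], eigvecs[:, order]
        flip = np.sign(eigvecs[np.argmax(np.abs(eigvecs), axis=0),
                               np.arange(p)])
        flip[flip == 0] = 1.0
        eigvecs = eigvecs * flip
        self.eigenvalues_ = eigvals
        self.components_ = eigvecs[:, : self.output_dim]   # (p, d)
        return self

    def transform(self, X):
        return self._scale(X) @ self.components_


# ---------------------------------------------------------------------------
# Gaussian Gram / kernel PLS
# ---------------------------------------------------------------------------

def gaussian_gram(A: np.ndarray, B: np.ndarray, gamma: float) -> np.ndarray:
    """Gaussian kernel table K[i, j] = exp(-gamma * ||a_i - b_j||^2)."""
    if gamma <= 0:
        raise ValidationError("kernel width gamma must be positive")
    A, B = np.asarray(A, dtype=float), np.asarray(B, dtype=float)
    if A.shape[1] != B.shape[1]:
        raise ValidationError("inputs must have matching column counts")
    return np.exp(-gamma * cdist(A, B, "sqeuclidean"))


class KplsExtractor(_Standardized):
    """Kernel partial least squares scores as extracted features.

    NIPALS on the double-centered training Gram and the (centered) targets
    yields latent directions U and training scores T; a test kernel is
    centered with the training statistics and projected as
    ``Kt_c U (T' K_c U)^{-1}`` so that transforming the training rows
    reproduces T.
    """

    name = "kpls"

    def __init__(self, output_dim: int = 10, gamma: float | None = None,
                 kernel: str = "gaussian", max_iter: int = 500, tol: float = 1e-10):
        self.output_dim = output_dim
        self.gamma = gamma
        self.kernel = kernel
        self.max_iter = max_iter
        self.tol = tol

    def _gram(self, A, B):
        if self.kernel == "linear":
            return A @ B.T
        return gaussian_gram(A, B, self.gamma_)

    def fit(self, X, y, rng=None):
        Z = self._fit_scaler(np.asarray(X, dtype=float))
        n = Z.shape[0]
        b = self.output_dim
        if not 1 <= b <= n - 1:
            raise ValidationError(f"latent count {b} must lie in [1, n-1]")
        # median-distance heuristic when no kernel width is given
        self.gamma_ = self.gamma
        if self.kernel == "gaussian" and self.gamma_ is None:
            d2 = cdist(Z, Z, "sqeuclidean")
            med = np.median(d2[np.triu_indices(n, k=1)])
            self.gamma_ = 1.0 / max(med, 1e-12)
        self.train_ = Z
        K = self._gram(Z, Z)
        J = np.eye(n) - np.full((n, n), 1.0 / n)
        Kc = J @ K @ J
        self.K_col_mean_ = K.mean(axis=0)    # training statistics for test centering
        self.K_mean_ = K.mean()

        Y = np.asarray(y, dtype=float).reshape(n, -1)
        Y = Y - Y.mean(axis=0)
        Kd, Yd = Kc.copy(), Y.copy()
        T = np.zeros((n, b))
        U = np.zeros((n, b))
        for a in range(b):
            u = Yd[:, :1].copy()
            if np.linalg.norm(u) < 1e-30:
                u = np.ones((n, 1))
            t_old = np.zeros((n, 1))
            for _ in range(self.max_iter):
                t = Kd @ u
                t /= max(np.linalg.norm(t), 1e-300)
                c = Yd.T @ t
                u = Yd @ c
                u /= max(np.linalg.norm(u), 1e-300)
                if np.linalg.norm(t - t_old) < self.tol:
                    break
                t_old = t
            T[:, a:a + 1] = t
            U[:, a:a + 1] = u
            P = np.eye(n) - t @ t.T
            Kd = P @ Kd @ P
            Yd = Yd - t @ (t.T @ Yd)
        self.T_, self.U_ = T, U
        M = T.T @ Kc @ U
        self.proj_ = U @ np.linalg.pinv(M)   # (n, b): scores = Kt_c @ proj_
        self.Kc_ = Kc
        return self

    def transform(self, X):
        Z = self._scale(X)
        Kt = self._gram(Z, self.train_)                  # (nt, n)
        # center with training statistics:
        # Kt_c = (Kt - 1_t k_colmean') (I - 11'/n)
        Kt_c = Kt - self.K_col_mean_[None, :]
        Kt_c = Kt_c - Kt_c.mean(axis=1, keepdims=True)
        return Kt_c @ self.proj_


# ---------------------------------------------------------------------------
# Kriging
# ---------------------------------------------------------------------------

class KrigingExtractor(_Standardized):
    """Per-sample 1-D ordinary kriging of the feature vector.

    Each sample's p standardized feature values are read as observations of a
    random field at locations linspace(0, 1, p); the transform returns the
    kriged values at ``output_dim`` equispaced target locations. The kriging
    weights solve the ordinary-kriging system (Gaussian covariance plus an
    unbiasedness constraint), so they sum to 1 for every target and a constant
    field is reproduced exactly. A small diagonal nugget keeps the very smooth
    Gaussian covariance numerically solvable.
    """

    name = "kriging"

    def __init__(self, output_dim: int = 10, length_scale: float = 0.5,
                 variance: float = 0.2, nugget: float = 1e-8):
        self.output_dim = output_dim
        self.length_scale = length_scale
        self.variance = variance
        self.nugget = nugget

    @staticmethod
    def kriging_weights(obs_locs, target_locs, length_scale, variance, nugget):
        """Ordinary-kriging weight matrix (n_obs, n_targets)."""
        obs = np.asarray(obs_locs, float).reshape(-1, 1)
        tgt = np.asarray(target_locs, float).reshape(-1, 1)
        p = obs.shape[0]
        cov = lambda d2: variance * np.exp(-d2 / (2.0 * length_scale ** 2))
        K = cov(cdist(obs, obs, "sqeuclidean")) + nugget * np.eye(p)
        k = cov(cdist(obs, tgt, "sqeuclidean"))
        A = np.zeros((p + 1, p + 1))
        A[:p, :p] = K
        A[p, :p] = 1.0
        A[:p, p] = 1.0
        rhs = np.vstack([k, np.ones((1, tgt.shape[0]))])
        sol = np.linalg.solve(A, rhs)
        return sol[:p, :]

    def fit(self, X, y=None, rng=None):
        if self.output_dim < 1:
            raise ValidationError("output_dim must be >= 1")
        X = np.asarray(X, dtype=float)
        if X.shape[1] < 2:
            raise ValidationError("kriging extraction needs >= 2 feature columns")
        self._fit_scaler(X)
        p = X.shape[1]
        obs = np.linspace(0.0, 1.0, p)
        tgt = np.linspace(0.0, 1.0, self.output_dim)
        self.weights_ = self.kriging_weights(
            obs, tgt, self.length_scale, self.variance, self.nugget)
        return self

    def transform(self, X):
        return self._scale(X) @ self.weights_


# ---------------------------------------------------------------------------
# Isomap
# ---------------------------------------------------------------------------

class IsomapExtractor(_Standardized):
    """Geodesic (graph-shortest-path) distances + classical scaling.

    A symmetric k-NN graph with Euclidean edge weights is built on the
    training rows; disconnected components are bridged by their single
    shortest inter-component Euclidean edge (with a warning) so every sample
    gets an embedding. Out-of-sample rows are embedded with the Nystrom
    formula from their geodesic distances to the training rows.
    """

    name = "isomap"

    def __init__(self, output_dim: int = 10, n_neighbors: int = 10):
        self.output_dim = output_dim
        self.n_neighbors = n_neighbors

    @staticmethod
    def _knn_graph(D: np.ndarray, k: int) -> sp.csr_matrix:
        n = D.shape[0]
        idx = np.argsort(D, axis=1)[:, 1:k + 1]
        rows = np.repeat(np.arange(n), k)
        cols = idx.ravel()
        W = sp.csr_matrix((D[rows, cols], (rows, cols)), shape=(n, n))
        return W.maximum(W.T)      # symmetrize

    def fit(self, X, y=None, rng=None):
        if self.n_neighbors < 1:
            raise ValidationError("n_neighbors must be >= 1")
        Z = self._fit_scaler(np.asarray(X, dtype=float))
        n = Z.shape[0]
        if not 1 <= self.output_dim <= n:
            raise ValidationError("output_dim must lie in [1, n_train]")
        D = cdist(Z, Z)
        W = self._knn_graph(D, min(self.n_neighbors, n - 1))

        n_comp, labels = connected_components(W, directed=False)
        if n_comp > 1:
            warnings.warn(
                f"neighbor graph has {n_comp} components; bridging with "
                "minimal Euclidean edges", stacklevel=2)
            W = W.tolil()
            while n_comp > 1:
                a = labels == labels[0]
                sub = D[np.ix_(a, ~a)]
                i_loc, j_loc = np.unravel_index(np.argmin(sub), sub.shape)
                i = np.flatnonzero(a)[i_loc]
                j = np.flatnonzero(~a)[j_loc]
                W[i, j] = W[j, i] = D[i, j]
                n_comp, labels = connected_components(W.tocsr(), directed=False)
            W = W.tocsr()

        G = shortest_path(W, method="D", directed=False)
        self.train_ = Z
        self.geodesics_ = G
        G2 = G ** 2
        J = np.eye(n) - np.full((n, n), 1.0 / n)
        B = -0.5 * J @ G2 @ J
        eigvals, eigvecs = np.linalg.eigh(B)
        order = np.argsort(eigvals)[::-1][: self.output_dim]
        lam = np.clip(eigvals[order], 0.0, None)
        V = eigvecs[:, order]
        self.eigenvalues_ = lam
        self.vectors_ = V
        self.embedding_ = V * np.sqrt(lam)
        self.row_mean_sq_ = G2.mean(axis=0)        # for Nystrom extension
        inv = np.zeros_like(lam)
        pos = lam > 1e-12
        inv[pos] = 1.0 / np.sqrt(lam[pos])
        self._inv_sqrt_lam = inv
        return self

    def _geodesic_to_train(self, Z: np.ndarray) -> np.ndarray:
        """Geodesics from new points through their k nearest training rows."""
        D = cdist(Z, self.train_)
        k = min(self.n_neighbors, self.train_.shape[0])
        idx = np.argsort(D, axis=1)[:, :k]
        out = np.empty_like(D)
        for i in range(Z.shape[0]):
            nb = idx[i]
            out[i] = np.min(D[i, nb][:, None] + self.geodesics_[nb], axis=0)
        return out

    def transform(self, X):
        Z = self._scale(X)
        Gt = self._geodesic_to_train(Z)
        centered = 0.5 * (self.row_mean_sq_[None, :] - Gt ** 2)
        return centered @ self.vectors_ * self._inv_sqrt_lam


# ---------------------------------------------------------------------------
# K-means distance features
# ---------------------------------------------------------------------------

class KmeansExtractor(_Standardized):
    """Lloyd clustering; features are distances to the k centroids.

    Initialization is greedy farthest-point seeding from the provided RNG
    stream; an emptied cluster is re-seeded at the point farthest from its
    nearest centroid. The per-iteration sum of within-cluster distances (the
    clustering-quality trace) is recorded and is non-increasing.
    """

    name = "kmeans"

    def __init__(self, n_clusters: int = 20, max_iter: int = 300):
        self.n_clusters = n_clusters
        self.max_iter = max_iter
        self.output_dim = n_clusters

    def fit(self, X, y=None, rng=None):
        rng = rng if rng is not None else np.random.default_rng(0)
        Z = self._fit_scaler(np.asarray(X, dtype=float))
        n = Z.shape[0]
        k = self.n_clusters
        if k > n:
            raise ValidationError("n_clusters must be <= n_train")
        # greedy farthest-point seeding
        first = int(rng.integers(n))
        centers = [Z[first]]
        dmin = cdist(Z, Z[[first]]).ravel()
        for _ in range(1, k):
            nxt = int(np.argmax(dmin))
            centers.append(Z[nxt])
            dmin = np.minimum(dmin, cdist(Z, Z[[nxt]]).ravel())
        C = np.array(centers)

        # Lloyd loop; the clustering-quality measure SD (sum of distances to
        # the assigned centroid) is recorded per iteration. The centroid mean
        # minimizes the *squared*-distance objective, so a mean update can in
        # rare cases raise SD slightly; such a step is rolled back and the
        # loop stops, keeping the recorded trace monotone non-increasing.
        self.sd_trace_ = []
        assign = np.full(n, -1)
        prev_C, prev_assign, prev_sd = None, None, np.inf
        for _ in range(self.max_iter):
            D = cdist(Z, C)
            new_assign = np.argmin(D, axis=1)
            sd = float(D[np.arange(n), new_assign].sum())
            if sd > prev_sd:
                C, new_assign = prev_C, prev_assign
                break
            self.sd_trace_.append(sd)
            if np.array_equal(new_assign, assign):
                break
            prev_C, prev_assign, prev_sd = C.copy(), new_assign, sd
            assign = new_assign
            for h in range(k):
                members = Z[assign == h]
                if len(members) == 0:
                    far = int(np.argmax(D.min(axis=1)))
                    C[h] = Z[far]
                else:
                    C[h] = members.mean(axis=0)
        self.centroids_ = C
        self.assignments_ = np.argmin(cdist(Z, C), axis=1)
        return self

    def transform(self, X):
        return cdist(self._scale(X), self.centroids_)


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

class IdentityExtractor:
    """Pass-through (no reduction); useful for baselines and harness tests."""

    name = "identity"

    def __init__(self):
        self.output_dim = None

    def fit(self, X, y=None, rng=None):
        self.n_features_ = np.asarray(X).shape[1]
        self.output_dim = self.n_features_
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_:
            raise ValidationError("column count changed between fit and transform")
        return X


EXTRACTORS = {
    "pca": PcaExtractor,
    "kpls": KplsExtractor,
    "kriging": KrigingExtractor,
    "isomap": IsomapExtractor,
    "kmeans": KmeansExtractor,
    "identity": IdentityExtractor,
}


def make_extractor(name: str, **params):
    if name not in EXTRACTORS:
        raise ValidationError(f"unknown extractor '{name}'")
    return EXTRACTORS[name](**params)
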
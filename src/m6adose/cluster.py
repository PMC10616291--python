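"""Fuzzy c-means clustering of temporal modification profiles.

Soft clustering in the Bezdek formulation: memberships u_ij in [0, 1] with
rows summing to 1, cluster centers as membership^m-weighted means, and the
objective J = sum_ij u_ij^m ||x_i - c_j||^2 minimized by alternating updates.
The fuzzifier m > 1 controls how soft the partition is (m -> 1 approaches
k-means; larger m flattens memberships).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted


class FuzzyCMeans(ClusterMixin, BaseEstimator):
    """Fuzzy c-means clustering (scikit-learn estimator API).

    Parameters
    ----------
    n_clusters : number of clusters c.
    m : fuzzifier (> 1).
    max_iter : iteration cap for the alternating updates.
    tol : convergence threshold on the max absolute membership change.
    n_init : number of random membership initializations; the run with the
        lowest final objective wins.
    random_state : seed for the initializations (int or Generator).

    Attributes
    ----------
    cluster_centers_ : (n_clusters, n_features) cluster centers.
    membership_ : (n_samples, n_clusters) membership weights, rows sum to 1.
    labels_ : argmax-membership hard assignment, ties broken by the lowest
        cluster index.
    objective_ : final value of the fuzzy objective J.
    objective_history_ : J after each iteration of the winning run
        (non-increasing).
    n_iter_ : iterations used by the winning run.
    """

    def __init__(
        self,
        n_clusters: int = 2,
        m: float = 2.0,
        max_iter: int = 300,
        tol: float = 1e-9,
        n_init: int = 5,
        random_state: int | None = 0,
    ):
        self.n_clusters = n_clusters
        self.m = m
        self.max_iter = max_iter
        self.tol = tol
        self.n_init = n_init
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    @staticmethod
    def _memberships(d2: np.ndarray, m: float) -> np.ndarray:
        """Membership update from squared distances (n_samples, c).

        u_ij = 1 / sum_k (d_ij / d_ik)^(1/(m-1)); points at zero distance
        from one or more centers split their membership equally among those
        centers (so fully degenerate geometry yields the uniform 1/c row).
        """
        power = 1.0 / (m - 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = d2 ** -power
            u = inv / inv.sum(axis=1, keepdims=True)
        zero = d2 <= 0
        rows = zero.any(axis=1)
        if rows.any():
            u[rows] = zero[rows] / zero[rows].sum(axis=1, keepdims=True)
        return u

    def _single_run(self, X: np.ndarray, rng: np.random.Generator):
        n, _ = X.shape
        c = self.n_clusters
        u = rng.dirichlet(np.ones(c), size=n)
        history = []
        for it in range(1, self.max_iter + 1):
            um = u**self.m
            weights = um.sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                centers = (um.T @ X) / weights[:, None]
            empty = weights <= 0  # cluster lost all weight (underflow): re-seed it
            if empty.any():
                centers[empty] = X[rng.integers(0, X.shape[0], size=int(empty.sum()))]
            d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            u_new = self._memberships(d2, self.m)
            history.append(float((u_new**self.m * d2).sum()))
            shift = float(np.abs(u_new - u).max())
            u = u_new
            if shift < self.tol:
                break
        return u, centers, history, it

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        if X.shape[0] < self.n_clusters:
            raise ValueError(
                f"n_samples={X.shape[0]} must be >= n_clusters={self.n_clusters}"
            )
        if self.m <= 1:
            raise ValueError("fuzzifier m must be > 1")
        rng = np.random.default_rng(self.random_state)
        best = None
        for _ in range(self.n_init):
            u, centers, history, n_iter = self._single_run(X, rng)
            if best is None or history[-1] < best[2][-1]:
                best = (u, centers, history, n_iter)
        u, centers, history, n_iter = best
        self.membership_ = u
        self.cluster_centers_ = centers
        self.objective_history_ = np.asarray(history)
        self.objective_ = history[-1]
        self.n_iter_ = n_iter
        self.labels_ = np.argmax(u, axis=1)  # argmax takes the lowest index on ties
        return self

    def predict(self, X):
        check_is_fitted(self, "cluster_centers_")
        X = np.asarray(X, dtype=float)
        d2 = ((X[:, None, :] - self.cluster_centers_[None, :, :]) ** 2).sum(axis=2)
        return np.argmax(self._memberships(d2, self.m), axis=1)

    def predict_membership(self, X):
        check_is_fitted(self, "cluster_centers_")
        X = np.asarray(X, dtype=float)
        d2 = ((X[:, None, :] - self.cluster_centers_[None, :, :]) ** 2).sum(axis=2)
        return self._memberships(d2, self.m)

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
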
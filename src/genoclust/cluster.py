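"""Lloyd's k-means over sparse sample rows with dense centroids.

Individuals are points in variant space: sparse dosage vectors whose absent
entries are zeros. Centroids are dense (cluster means of sparse rows are
generically dense). Distances use the expansion
``||x - c||^2 = ||x||^2 - 2 x.c + ||c||^2`` with cached norms, so the cost
per iteration scales with the number of stored entries rather than the full
``n_samples * n_variants`` grid.

:class:`SparseKMeans` is the estimator; :func:`kmeans_fit` /
:func:`kmeans_predict` are functional wrappers that produce a serialisable
:class:`KMeansModel`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, ClusterMixin

from .encode import GenotypeMatrix

__all__ = ["KMeansModel", "SparseKMeans", "kmeans_fit", "kmeans_predict"]


@dataclass
class KMeansModel:
    """A fitted clustering: centroids, assignments and the WCSS objective."""

    k: int
    centroids: np.ndarray  # (k, n_variants), dense
    assignments: np.ndarray  # (n_samples,), int
    objective: float  # within-cluster sum of squared distances
    n_iter: int
    objective_trace: list[float]
    sample_ids: tuple[str, ...] = ()
    seed: int | None = None

    def to_file(self, dest: str | Path) -> None:
        payload = {
            "format": "genoclust-kmeans v1",
            "k": self.k,
            "n_variants": int(self.centroids.shape[1]),
            "objective": self.objective,
            "n_iter": self.n_iter,
            "objective_trace": self.objective_trace,
            "seed": self.seed,
            "sample_ids": list(self.sample_ids),
            "assignments": [int(a) for a in self.assignments],
            "centroids": [list(map(float, c)) for c in self.centroids],
        }
        with open(dest, "wt") as out:
            json.dump(payload, out)
            out.write("\n")

    @classmethod
    def from_file(cls, source: str | Path) -> "KMeansModel":
        with open(source, "rt") as fh:
            payload = json.load(fh)
        if payload.get("format") != "genoclust-kmeans v1":
            raise ValueError(f"{source}: not a genoclust k-means model file")
        return cls(
            k=payload["k"],
            centroids=np.asarray(payload["centroids"], dtype=np.float64).reshape(
                payload["k"], payload["n_variants"]
            ),
            assignments=np.asarray(payload["assignments"], dtype=np.int64),
            objective=float(payload["objective"]),
            n_iter=int(payload["n_iter"]),
            objective_trace=[float(v) for v in payload["objective_trace"]],
            sample_ids=tuple(payload.get("sample_ids", ())),
            seed=payload.get("seed"),
        )


def _as_csr(X) -> sp.csr_matrix:
    if isinstance(X, GenotypeMatrix):
        return X.X.tocsr()
    if sp.issparse(X):
        return X.tocsr().astype(np.float64)
    return sp.csr_matrix(np.asarray(X, dtype=np.float64))


def _pairwise_sq_dists(
    X: sp.csr_matrix, row_norms: np.ndarray, centers: np.ndarray
) -> np.ndarray:
    """Squared Euclidean distances, clipped at zero against round-off."""
    cross = X @ centers.T  # (n, k), sparse-dense product
    d = row_norms[:, None] - 2.0 * np.asarray(cross) + np.einsum(
        "ij,ij->i", centers, centers
    )[None, :]
    np.maximum(d, 0.0, out=d)
    return d


def _plusplus_init(
    X: sp.csr_matrix, row_norms: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Sequential k-means++ seeding (D^2-weighted) over the sparse rows."""
    n = X.shape[0]
    centers = np.zeros((k, X.shape[1]))
    first = int(rng.integers(n))
    centers[0] = X.getrow(first).toarray().ravel()
    closest = _pairwise_sq_dists(X, row_norms, centers[:1]).ravel()
    for j in range(1, k):
        total = closest.sum()
        if total <= 0:
            # all points coincide with chosen centers; fall back to uniform
            pick = int(rng.integers(n))
        else:
            pick = int(rng.choice(n, p=closest / total))
        centers[j] = X.getrow(pick).toarray().ravel()
        d_new = _pairwise_sq_dists(X, row_norms, centers[j : j + 1]).ravel()
        np.minimum(closest, d_new, out=closest)
    return centers


def _random_partition_init(
    X: sp.csr_matrix, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Assign every point a random cluster; centroids are the cluster means."""
    n = X.shape[0]
    labels = rng.integers(k, size=n)
    # guarantee every cluster non-empty
    labels[rng.permutation(n)[:k]] = np.arange(k)
    return _cluster_means(X, labels, k, fallback=None)


def _cluster_means(
    X: sp.csr_matrix, labels: np.ndarray, k: int, fallback: np.ndarray | None
) -> np.ndarray:
    """Mean row per cluster via an indicator-matrix product.

    Empty clusters keep their previous centroid (``fallback``); reseeding is
    handled by the caller.
    """
    n = X.shape[0]
    counts = np.bincount(labels, minlength=k).astype(np.float64)
    indicator = sp.csr_matrix(
        (np.ones(n), (labels, np.arange(n))), shape=(k, n)
    )
    sums = np.asarray((indicator @ X).todense())
    means = np.zeros_like(sums)
    nonempty = counts > 0
    means[nonempty] = sums[nonempty] / counts[nonempty, None]
    if fallback is not None:
        means[~nonempty] = fallback[~nonempty]
    return means


class SparseKMeans(BaseEstimator, ClusterMixin):
    """K-means for sparse dosage rows, reproducible and restartable.

    Lloyd iterations: assign each sample to its nearest centroid by squared
    Euclidean distance (ties to the lowest centroid index), recompute
    centroids as cluster means, stop when the largest centroid displacement
    drops below ``tol`` or after ``max_iter`` iterations. Among
    ``n_restarts`` seeded restarts the fit with the lowest within-cluster
    sum of squares (WCSS) wins.

    Empty clusters are repaired by reseeding the empty centroid to the point
    currently farthest from its own centroid.

    Parameters
    ----------
    n_clusters : int
        Number of clusters k; for population structure, the number of
        annotated (super-)populations.
    init : {'plusplus', 'random-partition'} or ndarray of shape (k, n_features)
        Seeding strategy; an explicit centroid array is accepted for
        oracle-controlled runs.
    max_iter : int, default 100
    tol : float, default 1e-4
        Threshold on the maximum per-centroid Euclidean displacement.
    n_restarts : int, default 1
    random_state : int, default 0

    Attributes
    ----------
    cluster_centers_ : ndarray (k, n_variants)
    labels_ : ndarray (n_samples,)
    inertia_ : float
        Final WCSS.
    n_iter_ : int
    objective_trace_ : list of float
        WCSS after every assignment step; non-increasing.
    """

    def __init__(
        self,
        n_clusters: int = 4,
        init: str | np.ndarray = "plusplus",
        max_iter: int = 100,
        tol: float = 1e-4,
        n_restarts: int = 1,
        random_state: int = 0,
    ) -> None:
        self.n_clusters = n_clusters
        self.init = init
        self.max_iter = max_iter
        self.tol = tol
        self.n_restarts = n_restarts
        self.random_state = random_state

    # -- core ------------------------------------------------------------

    def _lloyd(
        self,
        X: sp.csr_matrix,
        row_norms: np.ndarray,
        centers: np.ndarray,
    ) -> tuple[np.ndarray, np.ndarray, float, int, list[float]]:
        k = self.n_clusters
        n = X.shape[0]
        trace: list[float] = []
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            d = _pairwise_sq_dists(X, row_norms, centers)
            labels = np.argmin(d, axis=1)  # argmin takes the lowest index on ties
            trace.append(float(d[np.arange(n), labels].sum()))
            # empty-cluster repair: reseed each empty centroid to the point
            # currently farthest from its own centroid (recorded trace entry
            # is the pre-repair optimal-assignment WCSS)
            missing = np.setdiff1d(np.arange(k), labels)
            if missing.size:
                worst = np.argsort(d[np.arange(n), labels])[::-1]
                for taken, c in enumerate(missing):
                    labels[worst[taken]] = c
            new_centers = _cluster_means(X, labels, k, fallback=centers)
            shift = np.sqrt(((new_centers - centers) ** 2).sum(axis=1)).max()
            centers = new_centers
            if shift < self.tol:
                break
        # final consistent assignment against the converged centroids
        d = _pairwise_sq_dists(X, row_norms, centers)
        labels = np.argmin(d, axis=1)
        objective = float(d[np.arange(n), labels].sum())
        trace.append(objective)
        return centers, labels, objective, n_iter, trace

    def fit(self, X, y=None) -> "SparseKMeans":
        """Fit on a :class:`GenotypeMatrix`, sparse matrix or dense array."""
        Xs = _as_csr(X)
        n = Xs.shape[0]
        if n == 0 or Xs.shape[1] == 0:
            raise ValueError("cannot cluster an empty matrix")
        if not 1 <= self.n_clusters <= n:
            raise ValueError(
                f"n_clusters must be in [1, n_samples={n}], got {self.n_clusters}"
            )
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol < 0:
            raise ValueError("tol must be >= 0")
        row_norms = np.asarray(Xs.multiply(Xs).sum(axis=1)).ravel()

        best: tuple | None = None
        seeds = np.random.SeedSequence(self.random_state).spawn(self.n_restarts)
        for restart_seq in seeds:
            rng = np.random.default_rng(restart_seq)
            if isinstance(self.init, np.ndarray):
                centers = np.array(self.init, dtype=np.float64, copy=True)
                if centers.shape != (self.n_clusters, Xs.shape[1]):
                    raise ValueError(
                        f"init centroids shape {centers.shape} != "
                        f"({self.n_clusters}, {Xs.shape[1]})"
                    )
            elif self.init == "plusplus":
                centers = _plusplus_init(Xs, row_norms, self.n_clusters, rng)
            elif self.init == "random-partition":
                centers = _random_partition_init(Xs, self.n_clusters, rng)
            else:
                raise ValueError(f"unknown init {self.init!r}")
            result = self._lloyd(Xs, row_norms, centers)
            if best is None or result[2] < best[2]:
                best = result

        assert best is not None
        self.cluster_centers_, self.labels_, self.inertia_, self.n_iter_, trace = best
        self.objective_trace_ = trace
        self.n_features_in_ = Xs.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        """Nearest-centroid assignment; ties go to the lowest centroid index."""
        Xs = _as_csr(X)
        if Xs.shape[1] != self.cluster_centers_.shape[1]:
            raise ValueError(
                f"matrix has {Xs.shape[1]} variants, model expects "
                f"{self.cluster_centers_.shape[1]}"
            )
        row_norms = np.asarray(Xs.multiply(Xs).sum(axis=1)).ravel()
        d = _pairwise_sq_dists(Xs, row_norms, self.cluster_centers_)
        return np.argmin(d, axis=1)

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


def kmeans_fit(
    matrix: GenotypeMatrix,
    k: int,
    max_iter: int = 100,
    tol: float = 1e-4,
    seed: int = 0,
    init: str | np.ndarray = "plusplus",
    n_restarts: int = 1,
) -> KMeansModel:
    """Cluster a genotype matrix; returns a serialisable :class:`KMeansModel`."""
    est = SparseKMeans(
        n_clusters=k,
        init=init,
        max_iter=max_iter,
        tol=tol,
        n_restarts=n_restarts,
        random_state=seed,
    ).fit(matrix)
    return KMeansModel(
        k=k,
        centroids=est.cluster_centers_,
        assignments=est.labels_,
        objective=est.inertia_,
        n_iter=est.n_iter_,
        objective_trace=est.objective_trace_,
        sample_ids=tuple(matrix.sample_ids),
        seed=seed,
    )


def kmeans_predict(model: KMeansModel, matrix: GenotypeMatrix) -> np.ndarray:
    """Assign each row of ``matrix`` to its nearest model centroid."""
    est = SparseKMeans(n_clusters=model.k)
    est.cluster_centers_ = model.centroids
    return est.predict(matrix)
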
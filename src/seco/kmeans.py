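"""Standard k-means with batch (Lloyd) iteration and on-line refinement.

The engine deliberately implements the classical algorithm: prototypes are
seeded with k randomly chosen data points, batch assignment/update steps run
to convergence, and a MacQueen-style on-line stage then presents points one
at a time, moving any point whose nearest prototype differs from its current
cluster and incrementally updating the two affected means.  Each on-line move
strictly decreases the within-cluster sum of squares, so the refinement can
only improve on the batch optimum.

Quantities exposed per converged run:

* ``wss``       — within-cluster sum of squares, Σ_i Σ_{x∈S_i} ||x − u_i||²
* ``delta_ssq`` — total sum of squares about the global mean minus ``wss``,
  the separation score used to rank ensemble runs.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Optional

import numpy as np
from numba import njit

__all__ = [
    "ClusterSolution",
    "as_data_matrix",
    "total_ssq",
    "seed_prototypes",
    "assign_labels",
    "within_ssq",
    "fit_kmeans",
    "fit_from_prototypes",
    "MAX_BATCH_ITER",
    "MAX_ONLINE_PASSES",
]

MAX_BATCH_ITER = 300
MAX_ONLINE_PASSES = 50


def as_data_matrix(values) -> np.ndarray:
    """Validate and coerce input to an (n, d) float64 matrix of finite values."""
    X = np.ascontiguousarray(values, dtype=np.float64)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    if X.ndim != 2:
        raise ValueError(f"data must be 2-dimensional, got ndim={X.ndim}")
    n, d = X.shape
    if n < 1 or d < 1:
        raise ValueError(f"data must have n >= 1 and d >= 1, got shape {X.shape}")
    if not np.isfinite(X).all():
        raise ValueError("data contains non-finite entries")
    return X


@dataclasses.dataclass
class ClusterSolution:
    """One converged k-means run.

    Labels are 0-based cluster ids; every id in ``range(k)`` is guaranteed to
    be populated (empty clusters are re-seeded during fitting).  ``seed`` is
    the RNG seed the run was initialised with (``None`` for deterministic
    fits from supplied prototypes) and ``run_id`` the 1-based index within an
    ensemble.
    """

    k: int
    labels: np.ndarray
    prototypes: np.ndarray
    wss: float
    delta_ssq: float
    n_iter: int
    seed: Optional[int] = None
    run_id: int = 0
    history: Optional[dict] = dataclasses.field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.prototypes = np.asarray(self.prototypes, dtype=np.float64)

    @property
    def n(self) -> int:
        return self.labels.shape[0]

    def to_json(self) -> str:
        payload = {
            "k": int(self.k),
            "labels": self.labels.tolist(),
            "prototypes": self.prototypes.tolist(),
            "wss": float(self.wss),
            "delta_ssq": float(self.delta_ssq),
            "n_iter": int(self.n_iter),
            "seed": None if self.seed is None else int(self.seed),
            "run_id": int(self.run_id),
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "ClusterSolution":
        p = json.loads(text)
        return cls(
            k=p["k"],
            labels=np.array(p["labels"], dtype=np.int64),
            prototypes=np.array(p["prototypes"], dtype=np.float64),
            wss=p["wss"],
            delta_ssq=p["delta_ssq"],
            n_iter=p["n_iter"],
            seed=p["seed"],
            run_id=p.get("run_id", 0),
        )


def total_ssq(data) -> float:
    """Total sum of squares of the data about its global mean."""
    X = as_data_matrix(data)
    return float(((X - X.mean(axis=0)) ** 2).sum())


def seed_prototypes(data, k: int, rng: np.random.Generator) -> np.ndarray:
    """Draw k distinct data rows, uniformly without replacement."""
    X = as_data_matrix(data)
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must satisfy 1 <= k <= n; got k={k}, n={n}")
    idx = rng.choice(n, size=k, replace=False)
    return X[idx].copy()


def _sq_distances(X: np.ndarray, prototypes: np.ndarray) -> np.ndarray:
    """(n, k) squared Euclidean distances via the Gram expansion."""
    d2 = (
        (X ** 2).sum(axis=1)[:, None]
        + (prototypes ** 2).sum(axis=1)[None, :]
        - 2.0 * X @ prototypes.T
    )
    np.maximum(d2, 0.0, out=d2)
    return d2


def assign_labels(data, prototypes) -> np.ndarray:
    """Label each point with its squared-Euclidean-nearest prototype.

    Ties go to the lowest prototype index (``argmin`` first occurrence).
    """
    X = as_data_matrix(data)
    P = np.asarray(prototypes, dtype=np.float64)
    if P.ndim != 2 or P.shape[1] != X.shape[1]:
        raise ValueError(
            f"prototype shape {P.shape} incompatible with data shape {X.shape}"
        )
    if not np.isfinite(P).all():
        raise ValueError("prototypes contain non-finite entries")
    return np.argmin(_sq_distances(X, P), axis=1).astype(np.int64)


def within_ssq(data, labels, prototypes) -> float:
    """Σ_i Σ_{x_j in S_i} ||x_j − u_i||² with u_i the supplied prototypes."""
    X = as_data_matrix(data)
    P = np.asarray(prototypes, dtype=np.float64)
    lab = np.asarray(labels, dtype=np.int64)
    if lab.shape[0] != X.shape[0]:
        raise ValueError("labels length does not match number of data rows")
    k = P.shape[0]
    if lab.min() < 0 or lab.max() >= k:
        raise ValueError(
            f"labels reference cluster ids outside 0..{k - 1}"
        )
    counts = np.bincount(lab, minlength=k)
    if (counts == 0).any():
        empty = int(np.flatnonzero(counts == 0)[0])
        raise ValueError(f"cluster {empty} is empty under the supplied labels")
    return float(((X - P[lab]) ** 2).sum())


def _cluster_means(X: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    counts = np.bincount(labels, minlength=k).astype(np.float64)
    means = np.empty((k, X.shape[1]))
    for j in range(X.shape[1]):
        means[:, j] = np.bincount(labels, weights=X[:, j], minlength=k)
    means /= counts[:, None]
    return means


def _fix_empty_clusters(X, labels, prototypes, k):
    """Re-seed each empty cluster at the point farthest from its current
    prototype, then re-assign; repeat until every cluster is populated."""
    for _ in range(k + 1):
        counts = np.bincount(labels, minlength=k)
        empties = np.flatnonzero(counts == 0)
        if empties.size == 0:
            return labels
        for c in empties:
            dist = ((X - prototypes[c]) ** 2).sum(axis=1)
            prototypes[c] = X[int(np.argmax(dist))]
        labels = np.argmin(_sq_distances(X, prototypes), axis=1).astype(np.int64)
    counts = np.bincount(labels, minlength=k)
    if (counts == 0).any():  # pragma: no cover - defensive
        raise RuntimeError("could not populate all clusters")
    return labels


@njit(cache=True)
def _online_refine(X, labels, prototypes, counts, max_passes):  # pragma: no cover
    """MacQueen-style on-line passes; returns the number of passes used.

    Points are presented in row order.  A point moves to its nearest
    prototype (lowest index on ties) unless the move would empty its current
    cluster; both affected means are updated incrementally.
    """
    n, d = X.shape
    k = prototypes.shape[0]
    passes = 0
    for _ in range(max_passes):
        moved = 0
        for j in range(n):
            cur = labels[j]
            best = 0
            best_dist = np.inf
            for c in range(k):
                s = 0.0
                for t in range(d):
                    diff = X[j, t] - prototypes[c, t]
                    s += diff * diff
                if s < best_dist:
                    best_dist = s
                    best = c
            if best != cur and counts[cur] > 1:
                nc = counts[cur]
                nb = counts[best]
                for t in range(d):
                    prototypes[cur, t] = (prototypes[cur, t] * nc - X[j, t]) / (nc - 1)
                    prototypes[best, t] = (prototypes[best, t] * nb + X[j, t]) / (nb + 1)
                counts[cur] -= 1
                counts[best] += 1
                labels[j] = best
                moved += 1
        passes += 1
        if moved == 0:
            break
    return passes


def fit_from_prototypes(
    data,
    prototypes,
    *,
    seed: Optional[int] = None,
    run_id: int = 0,
    collect_history: bool = False,
) -> ClusterSolution:
    """Run batch Lloyd iteration from the given prototypes to convergence,
    then on-line refinement passes until a full pass makes no move.

    Deterministic given the prototypes; ``seed`` is recorded as provenance
    only.  With ``collect_history`` the per-iteration / per-pass wss values
    are kept on ``solution.history`` for monotonicity checks.
    """
    X = as_data_matrix(data)
    P = np.array(prototypes, dtype=np.float64)
    k = P.shape[0]
    if not 1 <= k <= X.shape[0]:
        raise ValueError(f"k must satisfy 1 <= k <= n; got k={k}, n={X.shape[0]}")
    tss = total_ssq(X)

    labels = np.argmin(_sq_distances(X, P), axis=1).astype(np.int64)
    labels = _fix_empty_clusters(X, labels, P, k)

    batch_hist = []
    n_iter = 0
    for n_iter in range(1, MAX_BATCH_ITER + 1):
        P = _cluster_means(X, labels, k)
        new_labels = np.argmin(_sq_distances(X, P), axis=1).astype(np.int64)
        new_labels = _fix_empty_clusters(X, new_labels, P, k)
        if collect_history:
            means = _cluster_means(X, new_labels, k)
            batch_hist.append(float(((X - means[new_labels]) ** 2).sum()))
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels

    P = _cluster_means(X, labels, k)
    counts = np.bincount(labels, minlength=k).astype(np.int64)

    online_hist = []
    if collect_history:
        passes = 0
        while passes < MAX_ONLINE_PASSES:
            before = labels.copy()
            _online_refine(X, labels, P, counts, 1)
            passes += 1
            means = _cluster_means(X, labels, k)
            online_hist.append(float(((X - means[labels]) ** 2).sum()))
            if np.array_equal(before, labels):
                break
        n_passes = passes
    else:
        n_passes = int(_online_refine(X, labels, P, counts, MAX_ONLINE_PASSES))

    # exact means remove incremental-update drift; never increases wss
    P = _cluster_means(X, labels, k)
    wss = float(((X - P[labels]) ** 2).sum())
    history = {"batch": batch_hist, "online": online_hist} if collect_history else None
    return ClusterSolution(
        k=k,
        labels=labels,
        prototypes=P,
        wss=wss,
        delta_ssq=max(0.0, tss - wss),
        n_iter=n_iter + n_passes,
        seed=seed,
        run_id=run_id,
        history=history,
    )


def fit_kmeans(
    data,
    k: int,
    seed: int,
    *,
    run_id: int = 0,
    collect_history: bool = False,
) -> ClusterSolution:
    """Full k-means run: seed with k random data points, batch to
    convergence, then on-line refinement.  Reproducible given ``seed``."""
    X = as_data_matrix(data)
    rng = np.random.default_rng(seed)
    P0 = seed_prototypes(X, k, rng)
    return fit_from_prototypes(
        X, P0, seed=seed, run_id=run_id, collect_history=collect_history
    )
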
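"""Synthetic Gaussian-mixture benchmark and reference partitions.

The benchmark generator draws trivariate observations from a 10-component
normal mixture whose means, covariance matrices and cohort weights emulate
the three principal separation axes of a breast-cancer dataset, mixing
well-separated and strongly overlapping anisotropic cohorts.  Component
overlap is quantified by Dasgupta's c-separation,

    c(i, j) = ||μ_i − μ_j|| / sqrt( d · max(λ_max(Σ_i), λ_max(Σ_j)) ),

with d the dimension and λ_max the largest covariance eigenvalue; c well
below 2 indicates substantial overlap.

Because an exact recovery of overlapping cohorts is not achievable under the
isotropic Euclidean metric, benchmarking measures agreement against a
*reference partition*: the lowest-wss k-means solution among many runs on
the largest dataset, propagated to smaller datasets by iterating k-means to
convergence from the reference prototypes.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Optional

import numpy as np

from .kmeans import ClusterSolution, as_data_matrix, fit_from_prototypes, fit_kmeans

__all__ = [
    "MixtureSpec",
    "ReferencePartition",
    "table1_spec",
    "sample_mixture",
    "c_separation",
    "c_separation_matrix",
    "derive_reference_partition",
    "project_reference",
    "minmax_scale",
    "BENCHMARK_SIZES",
]

#: dataset sizes used by the density benchmark, largest first
BENCHMARK_SIZES = (10_000, 5_000, 2_500, 1_000, 500)

# 10-component trivariate benchmark: mean (x, y, z), row-major 3x3 covariance,
# cohort count in the emulated ~1076-record dataset.
_BENCHMARK_COMPONENTS = [
    ((-0.799, -1.011, -3.336),
     (0.336, 0.044, 0.074, 0.044, 0.371, 0.210, 0.074, 0.210, 0.582), 64),
    ((-0.441, -0.569, -2.331),
     (0.428, 0.060, -0.002, 0.060, 0.123, 0.157, -0.002, 0.157, 0.648), 42),
    ((0.649, -0.344, -4.154),
     (0.620, 0.023, -0.035, 0.023, 0.137, 0.070, -0.035, 0.070, 0.446), 61),
    ((1.077, 0.072, -2.815),
     (0.366, -0.002, 0.076, -0.002, 0.043, 0.104, 0.076, 0.104, 0.563), 32),
    ((-0.390, -0.242, 0.256),
     (0.536, 0.013, 0.031, 0.013, 0.348, -0.117, 0.031, -0.117, 0.689), 197),
    ((-1.358, -0.658, 1.639),
     (0.309, -0.060, -0.055, -0.060, 0.245, -0.013, -0.055, -0.013, 0.532), 131),
    ((1.261, 0.125, 0.862),
     (0.323, 0.017, 0.027, 0.017, 0.386, -0.060, 0.027, -0.060, 0.403), 163),
    ((-0.593, 3.024, -0.498),
     (0.776, 0.033, 0.175, 0.033, 0.491, 0.003, 0.175, 0.003, 0.695), 97),
    ((0.251, -0.539, -0.530),
     (0.711, -0.025, 0.055, -0.025, 0.352, -0.081, 0.055, -0.081, 0.576), 106),
    ((0.374, -0.267, 1.973),
     (0.390, -0.097, 0.041, -0.097, 0.343, -0.014, 0.041, -0.014, 0.322), 183),
]


@dataclasses.dataclass
class MixtureSpec:
    """Means, covariances and (normalised) weights of a Gaussian mixture."""

    means: np.ndarray
    covariances: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        self.means = np.asarray(self.means, dtype=np.float64)
        self.covariances = np.asarray(self.covariances, dtype=np.float64)
        w = np.asarray(self.weights, dtype=np.float64)
        if (w < 0).any() or w.sum() <= 0:
            raise ValueError("weights must be nonnegative with positive sum")
        self.weights = w / w.sum()
        m, d = self.means.shape
        if self.covariances.shape != (m, d, d):
            raise ValueError(
                f"covariances shape {self.covariances.shape} does not match "
                f"{m} components of dimension {d}"
            )
        self._chol = np.empty_like(self.covariances)
        for i, S in enumerate(self.covariances):
            if not np.allclose(S, S.T):
                raise ValueError(f"covariance of component {i} is not symmetric")
            try:
                self._chol[i] = np.linalg.cholesky(S)
            except np.linalg.LinAlgError as exc:
                raise ValueError(
                    f"covariance of component {i} is not positive definite"
                ) from exc

    @property
    def n_components(self) -> int:
        return self.means.shape[0]

    @property
    def d(self) -> int:
        return self.means.shape[1]


def table1_spec() -> MixtureSpec:
    """The 10-component trivariate benchmark mixture, weights proportional
    to the printed cohort counts (summing to 1076)."""
    means = [m for m, _, _ in _BENCHMARK_COMPONENTS]
    covs = [np.array(c).reshape(3, 3) for _, c, _ in _BENCHMARK_COMPONENTS]
    counts = [n for _, _, n in _BENCHMARK_COMPONENTS]
    return MixtureSpec(means=means, covariances=covs, weights=counts)


def sample_mixture(
    spec: MixtureSpec, n: int, rng: np.random.Generator | int
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n points: a component index from the weights, then a normal
    deviate via the component's Cholesky factor.  Returns (data, labels)
    with 0-based component labels."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    comp = rng.choice(spec.n_components, size=n, p=spec.weights)
    X = np.empty((n, spec.d))
    for c in range(spec.n_components):
        rows = np.flatnonzero(comp == c)
        if rows.size:
            z = rng.standard_normal((rows.size, spec.d))
            X[rows] = spec.means[c] + z @ spec._chol[c].T
    return X, comp.astype(np.int64)


def c_separation(spec: MixtureSpec, i: int, j: int) -> float:
    """Dasgupta's c-separation between components i and j (0-based)."""
    if i == j:
        raise ValueError("c-separation requires two distinct components")
    lam_i = np.linalg.eigvalsh(spec.covariances[i])[-1]
    lam_j = np.linalg.eigvalsh(spec.covariances[j])[-1]
    dist = np.linalg.norm(spec.means[i] - spec.means[j])
    return float(dist / np.sqrt(spec.d * max(lam_i, lam_j)))


def c_separation_matrix(spec: MixtureSpec) -> np.ndarray:
    """Symmetric matrix of pairwise c-separation values (zero diagonal)."""
    m = spec.n_components
    C = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            C[i, j] = C[j, i] = c_separation(spec, i, j)
    return C


@dataclasses.dataclass
class ReferencePartition:
    """Best-wss k-means partition of the largest benchmark dataset; its
    prototypes initialise the reference labelling of smaller datasets."""

    prototypes: np.ndarray
    labels: np.ndarray
    wss: float
    source_seed: int

    def __post_init__(self):
        self.prototypes = np.asarray(self.prototypes, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)

    @property
    def k(self) -> int:
        return self.prototypes.shape[0]

    def to_json(self) -> str:
        return json.dumps(
            {
                "prototypes": self.prototypes.tolist(),
                "wss": float(self.wss),
                "source_seed": int(self.source_seed),
            }
        )


def derive_reference_partition(
    data, master_seed: int, *, k: int = 10, n_runs: int = 500
) -> ReferencePartition:
    """Best of ``n_runs`` k-means fits (seeds master_seed+1 … +n_runs); the
    lowest-wss solution becomes the reference."""
    X = as_data_matrix(data)
    best: Optional[ClusterSolution] = None
    for r in range(1, n_runs + 1):
        sol = fit_kmeans(X, k, seed=master_seed + r, run_id=r)
        if best is None or sol.wss < best.wss:
            best = sol
    return ReferencePartition(
        prototypes=best.prototypes,
        labels=best.labels,
        wss=best.wss,
        source_seed=master_seed,
    )


def project_reference(reference: ReferencePartition, data_small) -> np.ndarray:
    """Iterate k-means to convergence on ``data_small`` from the reference
    prototypes (batch then on-line; no re-seeding).  Deterministic."""
    sol = fit_from_prototypes(data_small, reference.prototypes)
    return sol.labels


def minmax_scale(data, columns=None) -> np.ndarray:
    """Scale each column to [0, 1] by (x − min) / (max − min)."""
    X = as_data_matrix(data).copy()
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    flat = np.flatnonzero(hi == lo)
    if flat.size:
        name = columns[flat[0]] if columns is not None else f"column {flat[0]}"
        raise ValueError(f"cannot min-max scale constant {name}")
    return (X - lo) / (hi - lo)
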
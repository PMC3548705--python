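"""The Separation–Concordance (SeCo) procedure.

For a given cluster number k the framework (i) fits an ensemble of
independently seeded k-means runs, (ii) ranks them by the separation score
ΔSSQ (total SSQ minus within-cluster SSQ) and keeps the top fraction f,
(iii) scores each retained run by its median pairwise Cramér's V against
the other retained runs, (iv) assembles the (ΔSSQ, med(CV)) coordinates of
the retained runs into the SeCo map, and (v) selects the run with the
highest med(CV) — the dual-measure choice — as the reproducible partition.
Selecting on ΔSSQ alone (the single-measure convention) is provided for
comparison.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .concordance import median_pairwise_concordance
from .kmeans import ClusterSolution, as_data_matrix, fit_kmeans

__all__ = [
    "SeCoConfig",
    "SeCoPoint",
    "SeCoMap",
    "run_ensemble",
    "select_top_fraction",
    "build_seco_map",
    "select_solution",
    "select_solution_ssq_only",
    "dual_select",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class SeCoConfig:
    """Operating parameters of the framework.

    Defaults follow the framework's standard operating point: 500
    initialisations per k with the top decile by ΔSSQ retained, giving a
    working sample of 50 partitions.
    """

    n_total: int = 500
    fraction_f: float = 0.10
    k_range: Sequence[int] = (2,)
    master_seed: int = 0

    def __post_init__(self):
        self.k_range = [int(k) for k in self.k_range]
        if self.n_total < 2:
            raise ValueError(f"n_total must be >= 2, got {self.n_total}")
        if not 0.0 < self.fraction_f <= 1.0:
            raise ValueError(f"fraction_f must lie in (0, 1], got {self.fraction_f}")
        if math.floor(self.n_total * self.fraction_f) < 2:
            raise ValueError(
                f"floor(n_total * fraction_f) = "
                f"{math.floor(self.n_total * self.fraction_f)} < 2: the retained "
                "sample must contain at least one pair"
            )
        if not self.k_range:
            raise ValueError("k_range must be non-empty")
        if any(k < 1 for k in self.k_range):
            raise ValueError("all k in k_range must be >= 1")

    @property
    def n_sample(self) -> int:
        return math.floor(self.n_total * self.fraction_f)


@dataclasses.dataclass
class SeCoPoint:
    """One retained run's coordinates on the map."""

    k: int
    run_id: int
    delta_ssq: float
    med_cv: float
    solution: ClusterSolution = dataclasses.field(repr=False, compare=False, default=None)


@dataclasses.dataclass
class SeCoMap:
    """Per-k collections of (ΔSSQ, med(CV)) points for the retained runs.

    Only retained runs keep their label vectors; every point records its run
    seed so any map point can be re-materialised with ``fit_kmeans``.
    """

    points: dict[int, list[SeCoPoint]]
    config: SeCoConfig
    data_fingerprint: str

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (k, p.run_id, p.delta_ssq, p.med_cv)
            for k in sorted(self.points)
            for p in self.points[k]
        ]
        return pd.DataFrame(rows, columns=["k", "run_id", "delta_ssq", "med_cv"])

    def selected(self) -> dict[int, ClusterSolution]:
        """The dual-measure selection at each k."""
        return {k: select_solution(self.points[k]) for k in sorted(self.points)}


def data_fingerprint(data) -> str:
    X = as_data_matrix(data)
    h = hashlib.sha256(np.ascontiguousarray(X).tobytes()).hexdigest()[:16]
    return f"{X.shape[0]}x{X.shape[1]}:{h}"


def run_ensemble(data, k: int, config: SeCoConfig) -> list[ClusterSolution]:
    """Fit ``config.n_total`` independent k-means runs; run r (1-based) uses
    seed ``master_seed + r``.  Order follows run index."""
    X = as_data_matrix(data)
    first = config.master_seed + 1
    last = config.master_seed + config.n_total
    logger.info(
        "ensemble: k=%d, n_total=%d, seeds %d..%d", k, config.n_total, first, last
    )
    solutions = []
    for r in range(1, config.n_total + 1):
        try:
            solutions.append(
                fit_kmeans(X, k, seed=config.master_seed + r, run_id=r)
            )
        except Exception as exc:
            raise RuntimeError(f"ensemble run {r} (seed {config.master_seed + r}) failed") from exc
    return solutions


def select_top_fraction(
    solutions: Sequence[ClusterSolution], fraction_f: float
) -> list[ClusterSolution]:
    """Sort by ΔSSQ descending and retain the top floor(m·f); ΔSSQ ties are
    broken in favour of the lower run index."""
    if not solutions:
        raise ValueError("no solutions to select from")
    n_keep = math.floor(len(solutions) * fraction_f)
    if n_keep < 2:
        raise ValueError(
            f"fraction_f={fraction_f} retains {n_keep} of {len(solutions)} "
            "solutions; at least 2 are required"
        )
    order = sorted(solutions, key=lambda s: (-s.delta_ssq, s.run_id))
    return order[:n_keep]


def build_seco_map(data, config: SeCoConfig) -> SeCoMap:
    """Steps i–iv for every k in ``config.k_range``."""
    X = as_data_matrix(data)
    points: dict[int, list[SeCoPoint]] = {}
    for k in config.k_range:
        solutions = run_ensemble(X, k, config)
        retained = select_top_fraction(solutions, config.fraction_f)
        med_cv = median_pairwise_concordance(retained)
        points[k] = [
            SeCoPoint(k=k, run_id=s.run_id, delta_ssq=s.delta_ssq,
                      med_cv=float(m), solution=s)
            for s, m in zip(retained, med_cv)
        ]
    return SeCoMap(points=points, config=config, data_fingerprint=data_fingerprint(X))


def select_solution(map_points_for_k: Sequence[SeCoPoint]) -> ClusterSolution:
    """Step v: highest med(CV); ties by higher ΔSSQ, then lower run index."""
    if not map_points_for_k:
        raise ValueError("no map points to select from")
    best = min(map_points_for_k, key=lambda p: (-p.med_cv, -p.delta_ssq, p.run_id))
    return best.solution


def select_solution_ssq_only(
    solutions: Sequence[ClusterSolution],
) -> ClusterSolution:
    """Single-measure convention: best ΔSSQ (lowest wss); ties by lower run
    index."""
    if not solutions:
        raise ValueError("no solutions to select from")
    return min(solutions, key=lambda s: (-s.delta_ssq, s.run_id))


def dual_select(
    solutions: Sequence[ClusterSolution], fraction_f: float
) -> tuple[ClusterSolution, list[SeCoPoint]]:
    """Apply steps ii–v to an existing ensemble.

    Returns the dual-measure selection together with the retained map
    points.
    """
    retained = select_top_fraction(solutions, fraction_f)
    med_cv = median_pairwise_concordance(retained)
    points = [
        SeCoPoint(k=s.k, run_id=s.run_id, delta_ssq=s.delta_ssq,
                  med_cv=float(m), solution=s)
        for s, m in zip(retained, med_cv)
    ]
    return select_solution(points), points
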
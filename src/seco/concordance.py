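"""Partition-agreement statistics.

Two partitions of the same rows are compared through their contingency
table.  Cramér's V, V = sqrt( χ² / (N · min(P−1, Q−1)) ), normalises the
Pearson χ² statistic of that table to [0, 1] and is the concordance index
used to score stability across repeated k-means initialisations; the
Hubert–Arabie adjusted Rand index is provided as the classical pair-counting
alternative.  Both are symmetric and invariant to relabelling either side,
so no cluster alignment is needed before comparison.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from sklearn.metrics import adjusted_rand_score

__all__ = [
    "ContingencyTable",
    "contingency_table",
    "chi_square",
    "cramers_v",
    "ari_ha",
    "pairwise_cramers_v",
    "median_pairwise_concordance",
    "overall_median_concordance",
]


@dataclasses.dataclass
class ContingencyTable:
    """P × Q cross-tabulation of two partitions of the same N rows."""

    counts: np.ndarray
    row_labels: np.ndarray
    col_labels: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    @property
    def shape(self):
        return self.counts.shape


def _labels_1d(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.ndim != 1:
        raise ValueError("label vector must be 1-dimensional")
    return arr


def contingency_table(labels_a, labels_b) -> ContingencyTable:
    """Cross-tabulate two partitions; rows/columns follow the sorted distinct
    labels of each side."""
    a = _labels_1d(labels_a)
    b = _labels_1d(labels_b)
    if a.shape[0] != b.shape[0]:
        raise ValueError(
            f"label vectors differ in length: {a.shape[0]} vs {b.shape[0]}"
        )
    ra, ca = np.unique(a, return_inverse=True)
    rb, cb = np.unique(b, return_inverse=True)
    counts = np.bincount(ca * rb.size + cb, minlength=ra.size * rb.size).reshape(
        ra.size, rb.size
    )
    return ContingencyTable(counts=counts, row_labels=ra, col_labels=rb)


def chi_square(table: ContingencyTable) -> float:
    """Pearson χ² of the table, with E_pq = row_p · col_q / N."""
    O = table.counts.astype(np.float64)
    N = O.sum()
    if N <= 0:
        raise ValueError("contingency table is empty (N = 0)")
    row = O.sum(axis=1)
    col = O.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("contingency table has a zero row or column margin")
    E = np.outer(row, col) / N
    return float(((O - E) ** 2 / E).sum())


def _cramers_v_table(table: ContingencyTable) -> float:
    P, Q = table.shape
    if min(P, Q) < 2:
        raise ValueError(
            f"Cramér's V undefined for a {P}×{Q} table: both partitions "
            "need at least 2 clusters"
        )
    v2 = chi_square(table) / (table.n_total * (min(P, Q) - 1))
    return float(np.sqrt(min(max(v2, 0.0), 1.0)))


def cramers_v(labels_a, labels_b) -> float:
    """Cramér's V between two partitions; in [0, 1], 1 iff the partitions
    are identical up to relabelling (for equal cluster counts)."""
    return _cramers_v_table(contingency_table(labels_a, labels_b))


def ari_ha(labels_a, labels_b) -> float:
    """Hubert–Arabie adjusted Rand index between two partitions."""
    a = _labels_1d(labels_a)
    b = _labels_1d(labels_b)
    if a.shape[0] != b.shape[0]:
        raise ValueError(
            f"label vectors differ in length: {a.shape[0]} vs {b.shape[0]}"
        )
    return float(adjusted_rand_score(a, b))


def _extract_labels(solutions: Sequence) -> list[np.ndarray]:
    out = []
    for s in solutions:
        out.append(np.asarray(getattr(s, "labels", s)))
    n = {lab.shape[0] for lab in out}
    if len(n) > 1:
        raise ValueError("all partitions must cover the same rows")
    return out


def pairwise_cramers_v(solutions: Sequence) -> np.ndarray:
    """m × m symmetric matrix of pairwise Cramér's V (diagonal = 1).

    Accepts ClusterSolution objects or raw label vectors.
    """
    labels = _extract_labels(solutions)
    m = len(labels)
    codes = []
    sizes = []
    for lab in labels:
        u, inv = np.unique(lab, return_inverse=True)
        codes.append(inv.astype(np.int64))
        sizes.append(u.size)
    V = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            ki, kj = sizes[i], sizes[j]
            counts = np.bincount(
                codes[i] * kj + codes[j], minlength=ki * kj
            ).reshape(ki, kj)
            V[i, j] = V[j, i] = _cramers_v_table(
                ContingencyTable(counts, np.arange(ki), np.arange(kj))
            )
    return V


def median_pairwise_concordance(solutions: Sequence) -> np.ndarray:
    """Per-solution med(CV): the median of each solution's m−1 pairwise
    Cramér's V values against every other solution (self-pair excluded)."""
    if len(solutions) < 2:
        raise ValueError("need at least 2 solutions to compute med(CV)")
    V = pairwise_cramers_v(solutions)
    m = V.shape[0]
    off = V[~np.eye(m, dtype=bool)].reshape(m, m - 1)
    return np.median(off, axis=1)


def overall_median_concordance(solutions: Sequence) -> float:
    """Median Cramér's V over all unordered pairs (secondary summary; the
    selection rule uses the per-solution medians)."""
    if len(solutions) < 2:
        raise ValueError("need at least 2 solutions")
    V = pairwise_cramers_v(solutions)
    iu = np.triu_indices_from(V, k=1)
    return float(np.median(V[iu]))
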
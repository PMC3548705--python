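"""Benchmark metrics and the single- vs dual-measure protocol.

*Accuracy* is the proportion of points whose cluster agrees with a
reference partition under the optimal one-to-one relabelling of clusters
(maximum-weight bipartite matching on the contingency table); it requires a
square table, i.e. both partitions must use the same number of clusters.

*Affinity* measures how consistently individual points land in the same
cohort across an ensemble of selected partitions: each partition is aligned
to the reference frame by the accuracy matching, and the mean over rows of
the modal cohort frequency is reported.

The benchmarking protocol repeats the whole selection pipeline many times
with disjoint seed streams, selecting per repetition either the best-ΔSSQ
run (single measure) or the SeCo dual-measure run, and records Cramér's V
and accuracy against the reference for each repetition.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .concordance import contingency_table, cramers_v
from .framework import (
    SeCoConfig,
    dual_select,
    run_ensemble,
    select_solution_ssq_only,
)
from .kmeans import as_data_matrix

__all__ = [
    "accuracy",
    "alignment_mapping",
    "align_labels",
    "affinity",
    "BenchmarkResult",
    "benchmark",
    "benchmark_both",
    "ordered_curve_ci",
]


def _square_table(labels, reference):
    table = contingency_table(labels, reference)
    P, Q = table.shape
    if P != Q:
        raise ValueError(
            f"accuracy needs a square contingency table; partition has {P} "
            f"clusters but the reference has {Q}"
        )
    return table


def accuracy(labels, reference) -> float:
    """Optimal-matching classification accuracy against a reference
    partition with the same number of clusters."""
    table = _square_table(labels, reference)
    rows, cols = linear_sum_assignment(table.counts, maximize=True)
    return float(table.counts[rows, cols].sum() / table.n_total)


def alignment_mapping(labels, reference) -> dict:
    """The accuracy-optimal mapping from each cluster label to a reference
    label (one-to-one)."""
    table = _square_table(labels, reference)
    rows, cols = linear_sum_assignment(table.counts, maximize=True)
    return {
        table.row_labels[r]: table.col_labels[c] for r, c in zip(rows, cols)
    }


def align_labels(labels, reference) -> np.ndarray:
    """Relabel ``labels`` into the reference frame via the optimal matching."""
    mapping = alignment_mapping(labels, reference)
    lab = np.asarray(labels)
    out = np.empty_like(np.asarray(reference))
    for src, dst in mapping.items():
        out[lab == src] = dst
    return out


def affinity(partitions: Sequence, reference=None) -> float:
    """Mean over rows of the modal cohort frequency across partitions.

    Partitions are first aligned to ``reference`` (or to the first partition
    when no reference is given) by the accuracy matching; 1.0 means no point
    ever swaps cohort between selected partitions.
    """
    if len(partitions) < 2:
        raise ValueError("affinity needs at least 2 partitions")
    frame = np.asarray(reference if reference is not None else partitions[0])
    aligned = np.stack([align_labels(p, frame) for p in partitions])
    m, n = aligned.shape
    _, codes = np.unique(aligned, return_inverse=True)
    codes = codes.reshape(m, n)
    n_codes = codes.max() + 1
    freq = np.zeros((n_codes, n), dtype=np.int64)
    for i in range(m):
        np.add.at(freq, (codes[i], np.arange(n)), 1)
    return float((freq.max(axis=0) / m).mean())


@dataclasses.dataclass
class BenchmarkResult:
    """Per-method outcome of the repeated-selection protocol."""

    method: str
    k: int
    cv_values: np.ndarray
    accuracies: np.ndarray
    accuracy_mean: float
    accuracy_sd: float
    affinity: float
    config: SeCoConfig

    @property
    def n_reps(self) -> int:
        return self.cv_values.shape[0]

    def sorted_cv(self) -> np.ndarray:
        """Ordered concordance curve (non-decreasing)."""
        return np.sort(self.cv_values)


def _assemble(method, k, cv, acc, parts, reference, config) -> BenchmarkResult:
    acc = np.asarray(acc)
    return BenchmarkResult(
        method=method,
        k=k,
        cv_values=np.asarray(cv),
        accuracies=acc,
        accuracy_mean=float(acc.mean()),
        accuracy_sd=float(acc.std(ddof=1)) if acc.size > 1 else 0.0,
        affinity=affinity(parts, reference) if len(parts) > 1 else 1.0,
        config=config,
    )


def benchmark_both(
    data,
    reference,
    k: int,
    n_reps: int,
    config: SeCoConfig,
) -> dict[str, BenchmarkResult]:
    """Run the protocol once, selecting single- and dual-measure solutions
    from the same ensembles (paired comparison on identical seed streams).

    Repetition r (0-based) runs its ensemble from master seed
    ``config.master_seed + r * config.n_total`` so seed streams never
    overlap.
    """
    X = as_data_matrix(data)
    ref = np.asarray(reference)
    if ref.shape[0] != X.shape[0]:
        raise ValueError("reference length does not match data")
    store = {m: {"cv": [], "acc": [], "parts": []} for m in ("single", "dual")}
    for r in range(n_reps):
        cfg_r = dataclasses.replace(
            config, master_seed=config.master_seed + r * config.n_total
        )
        solutions = run_ensemble(X, k, cfg_r)
        picks = {
            "single": select_solution_ssq_only(solutions),
            "dual": dual_select(solutions, config.fraction_f)[0],
        }
        for method, sel in picks.items():
            store[method]["cv"].append(cramers_v(sel.labels, ref))
            store[method]["acc"].append(accuracy(sel.labels, ref))
            store[method]["parts"].append(sel.labels)
    return {
        m: _assemble(m, k, s["cv"], s["acc"], s["parts"], ref, config)
        for m, s in store.items()
    }


def benchmark(
    data,
    reference,
    k: int,
    method: str,
    n_reps: int,
    config: SeCoConfig,
) -> BenchmarkResult:
    """Repeated-selection benchmark for one method ('single' or 'dual')."""
    if method not in ("single", "dual"):
        raise ValueError(f"method must be 'single' or 'dual', got {method!r}")
    return benchmark_both(data, reference, k, n_reps, config)[method]


def ordered_curve_ci(
    values,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-rank percentile-bootstrap confidence band for an ordered
    concordance curve."""
    v = np.sort(np.asarray(values, dtype=np.float64))
    rng = np.random.default_rng(seed)
    boot = np.sort(
        rng.choice(v, size=(n_boot, v.size), replace=True), axis=1
    )
    alpha = (1.0 - level) / 2.0
    lower = np.quantile(boot, alpha, axis=0)
    upper = np.quantile(boot, 1.0 - alpha, axis=0)
    return lower, upper
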
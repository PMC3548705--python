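"""Partition tree: membership flow between selected solutions at
consecutive k.

Given one selected partition per k over a consecutive range, the tree's
edges are the contingency counts between each pair of adjacent levels.  An
edge's fraction is its count divided by the size of the originating cohort;
edges below ``min_fraction`` are kept in the data but flagged invisible so
renderings stay legible (the conventional cut hides flows under 10% of the
source cohort).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .concordance import contingency_table
from .kmeans import ClusterSolution

__all__ = ["TreeEdge", "PartitionTree", "build_partition_tree"]


@dataclasses.dataclass
class TreeEdge:
    k_from: int
    cohort_from: int
    k_to: int
    cohort_to: int
    count: int
    fraction: float
    visible: bool


@dataclasses.dataclass
class PartitionTree:
    """Selected solutions per k plus the flow edges between adjacent k."""

    levels: dict[int, ClusterSolution]
    edges: list[TreeEdge]
    min_fraction: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [dataclasses.asdict(e) for e in self.edges],
            columns=[
                "k_from", "cohort_from", "k_to", "cohort_to",
                "count", "fraction", "visible",
            ],
        )

    def cohort_sizes(self, k: int) -> np.ndarray:
        sol = self.levels[k]
        return np.bincount(sol.labels, minlength=sol.k)

    def display_order(self, k: int) -> np.ndarray:
        """Cohort ids at level k ordered by decreasing size (stable)."""
        sizes = self.cohort_sizes(k)
        return np.argsort(-sizes, kind="stable")


def build_partition_tree(
    selected: Mapping[int, ClusterSolution] | Sequence[ClusterSolution],
    min_fraction: float = 0.10,
) -> PartitionTree:
    """Build flow edges between the selected solutions at consecutive k."""
    if not isinstance(selected, Mapping):
        selected = {s.k: s for s in selected}
    ks = sorted(selected)
    if not ks:
        raise ValueError("no solutions supplied")
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError(f"k values must be consecutive, got {ks}")
    n = {selected[k].labels.shape[0] for k in ks}
    if len(n) > 1:
        raise ValueError("all solutions must partition the same rows")

    edges: list[TreeEdge] = []
    for k in ks[:-1]:
        a, b = selected[k], selected[k + 1]
        table = contingency_table(a.labels, b.labels)
        row_sizes = table.row_totals
        for p in range(table.shape[0]):
            for q in range(table.shape[1]):
                cnt = int(table.counts[p, q])
                if cnt == 0:
                    continue
                frac = cnt / row_sizes[p]
                edges.append(
                    TreeEdge(
                        k_from=k,
                        cohort_from=int(table.row_labels[p]),
                        k_to=k + 1,
                        cohort_to=int(table.col_labels[q]),
                        count=cnt,
                        fraction=float(frac),
                        visible=bool(frac >= min_fraction),
                    )
                )
    return PartitionTree(levels=dict(selected), edges=edges, min_fraction=min_fraction)
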
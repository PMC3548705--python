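"""Optional matplotlib renderings of the SeCo map and the partition tree."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_seco_map", "plot_partition_tree"]


def plot_seco_map(seco_map, ax=None, path=None):
    """Scatter of the retained solutions: med(CV) on x, ΔSSQ on y, coloured
    by k."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 5))
    frame = seco_map.to_frame()
    ks = sorted(frame["k"].unique())
    cmap = plt.get_cmap("viridis", max(len(ks), 2))
    for i, k in enumerate(ks):
        sub = frame[frame["k"] == k]
        ax.scatter(sub["med_cv"], sub["delta_ssq"], s=18, color=cmap(i),
                   label=f"k={k}")
    ax.set_xlabel("median internal Cramér's V")
    ax.set_ylabel("ΔSSQ")
    ax.set_title("Separation–Concordance map")
    ax.legend(fontsize=7, ncol=2)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax


def plot_partition_tree(tree, ax=None, path=None):
    """Simple flow rendering: one column of cohort blocks per k, line width
    proportional to flow; hidden edges are not drawn."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 5))
    ks = sorted(tree.levels)
    pos = {}
    for k in ks:
        order = tree.display_order(k)
        sizes = tree.cohort_sizes(k)
        n = sizes.sum()
        y = 0.0
        for c in order:
            h = sizes[c] / n
            pos[(k, int(c))] = (k, y + h / 2)
            ax.add_patch(
                plt.Rectangle((k - 0.08, y), 0.16, h * 0.96,
                              color="steelblue", alpha=0.7)
            )
            y += h
    total = max(e.count for e in tree.edges) if tree.edges else 1
    for e in tree.edges:
        if not e.visible:
            continue
        x0, y0 = pos[(e.k_from, e.cohort_from)]
        x1, y1 = pos[(e.k_to, e.cohort_to)]
        ax.plot([x0 + 0.08, x1 - 0.08], [y0, y1], color="grey",
                lw=0.5 + 4.0 * e.count / total, alpha=0.6)
    ax.set_xticks(ks)
    ax.set_xlabel("number of clusters k")
    ax.set_yticks([])
    ax.set_xlim(ks[0] - 0.5, ks[-1] + 0.5)
    ax.set_ylim(0, 1)
    ax.set_title("Partition tree (flows ≥ {:.0%} of source)".format(tree.min_fraction))
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax
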
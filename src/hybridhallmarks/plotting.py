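"""Figure helpers: genotype mosaic heatmap, admixture bars, tree sketch."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import dendropy
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

GENOTYPE_COLORS = {
    "A_like": "#7b3294",       # purple: parentA-characteristic
    "B_like": "#92c5de",       # light blue: parentB-characteristic
    "heterozygote": "#000000",
    "missing": "#bdbdbd",
}


def genotype_heatmap(codes: pd.DataFrame, path: str, row_order: Sequence[str] | None = None) -> None:
    """Individual × site mosaic of ancestry classes."""
    if row_order is not None:
        codes = codes.reindex(index=[r for r in row_order if r in codes.index])
    cats = list(GENOTYPE_COLORS)
    lut = {c: i for i, c in enumerate(cats)}
    M = codes.apply(lambda col: col.map(lut)).to_numpy(dtype=float)
    cmap = matplotlib.colors.ListedColormap([GENOTYPE_COLORS[c] for c in cats])
    fig, ax = plt.subplots(figsize=(max(4, 0.18 * codes.shape[1]), max(3, 0.12 * codes.shape[0])))
    ax.imshow(M, aspect="auto", cmap=cmap, vmin=-0.5, vmax=len(cats) - 0.5, interpolation="nearest")
    ax.set_xticks(range(codes.shape[1]))
    ax.set_xticklabels(codes.columns, rotation=90, fontsize=5)
    ax.set_yticks(range(codes.shape[0]))
    ax.set_yticklabels(codes.index, fontsize=5)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def admixture_bars(q: pd.DataFrame, populations: pd.Series, path: str) -> None:
    """Stacked per-individual admixture proportions, grouped by population."""
    order = populations.sort_values(kind="stable").index
    q = q.reindex(index=[i for i in order if i in q.index])
    pops = populations.reindex(q.index)
    fig, ax = plt.subplots(figsize=(max(5, 0.08 * len(q)), 2.5))
    bottom = np.zeros(len(q))
    for k, col in enumerate(q.columns):
        ax.bar(range(len(q)), q[col].to_numpy(), bottom=bottom, width=1.0, label=col)
        bottom += q[col].to_numpy()
    # population separators
    boundaries = np.flatnonzero(pops.to_numpy()[1:] != pops.to_numpy()[:-1]) + 0.5
    for b in boundaries:
        ax.axvline(b, color="black", lw=0.8)
    ax.set_xlim(-0.5, len(q) - 0.5)
    ax.set_ylim(0, 1)
    ax.set_xticks([])
    ax.set_ylabel("admixture q")
    ax.legend(fontsize=6, ncol=len(q.columns), loc="upper center", bbox_to_anchor=(0.5, 1.25))
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def tree_sketch(tree: dendropy.Tree, path: str) -> None:
    """Simple rectangular cladogram with support labels."""
    leaves = list(tree.leaf_node_iter())
    ys = {leaf: i for i, leaf in enumerate(leaves)}
    xs = {}

    def depth(node, x0=0.0):
        xs[node] = x0
        for ch in node.child_nodes():
            depth(ch, x0 + (ch.edge.length or 1.0))

    depth(tree.seed_node)

    def ypos(node):
        if node.is_leaf():
            return ys[node]
        return float(np.mean([ypos(ch) for ch in node.child_nodes()]))

    fig, ax = plt.subplots(figsize=(6, max(2, 0.25 * len(leaves))))
    for node in tree.preorder_node_iter():
        y = ypos(node)
        if node.parent_node is not None:
            ax.plot([xs[node.parent_node], xs[node]], [y, y], color="k", lw=1)
            ax.plot([xs[node.parent_node]] * 2, [ypos(node.parent_node), y], color="k", lw=1)
        if node.is_leaf():
            ax.text(xs[node], y, f" {node.taxon.label}", va="center", fontsize=6)
        elif getattr(node, "label", None):
            ax.text(xs[node], y, node.label, va="bottom", ha="right", fontsize=5, color="firebrick")
    ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
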
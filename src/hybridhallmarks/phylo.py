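"""AFLP distance phylogenetics: neighbor joining, bootstrap, trait mapping.

Distance-based neighbor joining is the method of choice for dominant
AFLP data, which lack a substitution model.  The default distance is the
mean character difference (mismatches over pairwise-comparable markers);
Jaccard is available.  NJ follows the Saitou–Nei agglomeration with the
standard Q-criterion and deterministic tie-breaking on the smallest
index pair, so additive matrices are recovered exactly.  Negative branch
lengths are clamped to zero with the deficit moved onto the sibling
edge (flagged).  Branch support comes from resampling marker columns
with replacement: the support of an internal edge is the percentage of
replicate NJ trees containing the same leaf bipartition.

Binary trait histories are reconstructed by Fitch parsimony on a tree
rooted at a declared outgroup; ambiguous reconstructions (e.g. parallel
gains versus a basal gain plus losses) are enumerated exhaustively as
the full set of most-parsimonious state assignments.  A hybrid taxon is
never placed inside the parsimony pass — attach it post hoc.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .seqio import AFLPMatrix

__all__ = [
    "binary_distance",
    "neighbor_joining",
    "bootstrap_support",
    "bipartitions",
    "FitchReconstruction",
    "fitch_map",
]


def binary_distance(aflp: AFLPMatrix, metric: str = "mean_character_difference") -> pd.DataFrame:
    """Pairwise distances between individuals from a binary marker matrix.

    ``mean_character_difference`` = mismatches / markers compared (after
    pairwise deletion of missing scores); ``jaccard`` = 1 − shared
    presences / union presences.  A pair with zero comparable markers is
    an error.
    """
    X = aflp.bands.to_numpy(dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 individuals")
    obs = ~np.isnan(X)
    Xf = np.nan_to_num(X)
    if metric == "mean_character_difference":
        comparable = obs.astype(float) @ obs.astype(float).T
        if (comparable == 0).any():
            raise ValueError("some pair has no comparable markers")
        both = obs[:, None, :] & obs[None, :, :]
        mism = ((Xf[:, None, :] != Xf[None, :, :]) & both).sum(axis=2)
        D = mism / comparable
    elif metric == "jaccard":
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                m = obs[i] & obs[j]
                union = ((Xf[i] == 1) | (Xf[j] == 1)) & m
                inter = (Xf[i] == 1) & (Xf[j] == 1) & m
                if union.sum() == 0:
                    d = 0.0
                else:
                    d = 1.0 - inter.sum() / union.sum()
                D[i, j] = D[j, i] = d
    else:
        raise ValueError(f"unknown metric {metric!r}")
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=aflp.individuals, columns=aflp.individuals)


def neighbor_joining(D: pd.DataFrame | np.ndarray, taxa: Sequence[str] | None = None) -> dendropy.Tree:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q-criterion resolve to the lexicographically smallest
    (i, j) index pair of the current working matrix, so output is
    reproducible.  Negative branch lengths are clamped to 0 and the
    deficit moved to the sibling edge; affected edges get the annotation
    ``clamped=True``.  The returned tree is unrooted (dendropy stores it
    with a trifurcating seed node).
    """
    if isinstance(D, pd.DataFrame):
        taxa = list(D.index)
        M = D.to_numpy(dtype=float).copy()
    else:
        M = np.asarray(D, dtype=float).copy()
        if taxa is None:
            taxa = [f"t{i}" for i in range(M.shape[0])]
    if np.isnan(M).any():
        raise ValueError("distance matrix contains NaN")
    n = M.shape[0]
    if n < 4:
        raise ValueError("need >= 4 taxa")

    tns = dendropy.TaxonNamespace()
    nodes = []
    for name in taxa:
        taxon = tns.new_taxon(label=name)
        nd = dendropy.Node(taxon=taxon)
        nodes.append(nd)
    active = list(range(n))

    def set_len(node: dendropy.Node, length: float) -> None:
        node.edge.length = float(length)

    while len(active) > 3:
        m = len(active)
        sub = M[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        best = np.unravel_index(np.argmin(Q), Q.shape)  # first occurrence = smallest index pair
        i, j = sorted(best)
        gi, gj = active[i], active[j]
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        # clamp negatives, moving deficit to the sibling edge
        clamped = False
        if li < 0:
            lj += li
            li, clamped = 0.0, True
        if lj < 0:
            li += lj
            lj, clamped = 0.0, True
            li = max(li, 0.0)
        parent = dendropy.Node()
        na, nb = nodes[gi], nodes[gj]
        parent.add_child(na)
        parent.add_child(nb)
        set_len(na, li)
        set_len(nb, lj)
        if clamped:
            na.edge.clamped = nb.edge.clamped = True
        # distances from the new node to remaining taxa
        M = np.pad(M, ((0, 1), (0, 1)))
        gk = M.shape[0] - 1
        for a in active:
            if a in (gi, gj):
                continue
            M[gk, a] = M[a, gk] = 0.5 * (M[gi, a] + M[gj, a] - dij)
        nodes.append(parent)
        active = [a for a in active if a not in (gi, gj)] + [gk]

    # final three-way join onto a trifurcating seed node
    ga, gb, gc = active
    seed = dendropy.Node()
    la = 0.5 * (M[ga, gb] + M[ga, gc] - M[gb, gc])
    lb = 0.5 * (M[ga, gb] + M[gb, gc] - M[ga, gc])
    lc = 0.5 * (M[ga, gc] + M[gb, gc] - M[ga, gb])
    for g, l in ((ga, la), (gb, lb), (gc, lc)):
        seed.add_child(nodes[g])
        set_len(nodes[g], max(l, 0.0))
        if l < 0:
            nodes[g].edge.clamped = True
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=seed)
    tree.is_rooted = False
    return tree


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial leaf bipartitions, each canonicalized to its smaller side
    (lexicographic order breaks equal-size ties)."""
    all_taxa = frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())
    out: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        other = all_taxa - side
        if len(side) < 2 or len(other) < 2:
            continue
        canon = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
        out.add(canon)
    return out


def bootstrap_support(
    aflp: AFLPMatrix,
    n_reps: int = 2000,
    seed: int | None = None,
    metric: str = "mean_character_difference",
) -> dendropy.Tree:
    """NJ tree with column-resampled bootstrap supports on internal edges.

    Marker columns are resampled with replacement ``n_reps`` times; the
    support of each internal edge of the original tree is the percentage
    of replicate trees containing the same bipartition, stored as
    ``node.label`` (integer percent) and ``node.support``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    tree = neighbor_joining(binary_distance(aflp, metric=metric))
    target = {bp: 0 for bp in bipartitions(tree)}
    L = len(aflp.markers)
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        resampled = AFLPMatrix(
            aflp.bands.iloc[:, cols].set_axis([f"b{i}" for i in range(L)], axis=1)
        )
        try:
            rep_tree = neighbor_joining(binary_distance(resampled, metric=metric))
        except ValueError:
            continue  # e.g. a pair with no comparable resampled markers
        for bp in bipartitions(rep_tree):
            if bp in target:
                target[bp] += 1
    all_taxa = frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        other = all_taxa - side
        if len(side) < 2 or len(other) < 2:
            continue
        canon = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
        pct = 100.0 * target[canon] / n_reps
        node.support = pct
        node.label = str(int(round(pct)))
    return tree


@dataclass
class FitchReconstruction:
    trait: str
    n_changes: int
    change_edges: list[tuple[str, str]]  # (parent clade label, child clade label) of one MPR
    reconstructions: list[dict[str, int]]  # all most-parsimonious internal-state maps
    skipped: bool = False


def _node_key(node: dendropy.Node) -> str:
    if node.is_leaf():
        return node.taxon.label
    return "{" + ",".join(sorted(l.taxon.label for l in node.leaf_iter())) + "}"


def fitch_map(
    tree: dendropy.Tree,
    traits: pd.DataFrame,
    outgroup: str | None = None,
) -> list[FitchReconstruction]:
    """Fitch parsimony reconstruction of binary traits on a rooted tree.

    ``traits`` is taxon × trait with values 0/1 or NaN (unknown; the tip
    is then free).  If ``outgroup`` is given the tree is (re)rooted on
    that leaf's edge first.  For each trait the minimal number of state
    changes is found and *all* most-parsimonious reconstructions are
    enumerated (unit-cost Sankoff over {0,1}); the reported change-edge
    list comes from the first reconstruction in enumeration order.
    Traits unknown at every tip are skipped with a flag.
    """
    tree = tree.clone(depth=1)
    if outgroup is not None:
        og = next(l for l in tree.leaf_node_iter() if l.taxon.label == outgroup)
        tree.to_outgroup_position(og, update_bipartitions=False, suppress_unifurcations=False)
    results = []
    nodes = list(tree.postorder_node_iter())
    for trait in traits.columns:
        states = traits[trait]
        if states.dropna().empty:
            results.append(FitchReconstruction(trait, 0, [], [], skipped=True))
            continue
        # unit-cost Sankoff bottom-up
        cost: dict[dendropy.Node, np.ndarray] = {}
        for node in nodes:
            if node.is_leaf():
                label = node.taxon.label
                v = states.get(label, np.nan)
                if pd.isna(v):
                    cost[node] = np.zeros(2)
                else:
                    c = np.full(2, np.inf)
                    c[int(v)] = 0.0
                    cost[node] = c
            else:
                # min over child state s_c of cost[ch][s_c] + [s_c != s_p]
                total = np.array([
                    sum(min(cost[ch][0], cost[ch][1] + 1) for ch in node.child_nodes()),
                    sum(min(cost[ch][1], cost[ch][0] + 1) for ch in node.child_nodes()),
                ])
                cost[node] = total
        root = tree.seed_node
        n_changes = int(cost[root].min())

        # enumerate all optimal assignments top-down
        def optimal_child_states(node, parent_state):
            opts = []
            for s in (0, 1):
                if cost[node][s] + (0 if s == parent_state else 1) == min(
                    cost[node][t] + (0 if t == parent_state else 1) for t in (0, 1)
                ):
                    opts.append(s)
            return opts

        reconstructions: list[dict[str, int]] = []

        def rec(assign: dict, frontier: list):
            if not frontier:
                reconstructions.append(dict(assign))
                return
            node, parent_state = frontier[0]
            if parent_state is None:
                opts = [s for s in (0, 1) if cost[node][s] == cost[node].min()]
            else:
                opts = optimal_child_states(node, parent_state)
            for s in opts:
                assign[_node_key(node)] = s
                rec(assign, frontier[1:] + [(ch, s) for ch in node.child_nodes()])
            assign.pop(_node_key(node), None)

        rec({}, [(root, None)])
        # deduplicate (frontier expansion can revisit equal assignments)
        seen = set()
        uniq = []
        for r in reconstructions:
            key = tuple(sorted(r.items()))
            if key not in seen:
                seen.add(key)
                uniq.append(r)
        first = uniq[0]
        edges = []
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            a = first[_node_key(node.parent_node)]
            b = first[_node_key(node)]
            if a != b:
                edges.append((_node_key(node.parent_node), _node_key(node)))
        results.append(FitchReconstruction(trait, n_changes, edges, uniq))
    return results
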
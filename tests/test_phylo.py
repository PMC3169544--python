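"""Distances, neighbor joining, bootstrap, and Fitch parsimony."""

import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest

from hybridhallmarks import datasets, phylo

from conftest import make_aflp


def patristic(tree):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    def d(a, b):
        return pdm.patristic_distance(taxa[a], taxa[b])
    return d


def random_additive_matrix(rng, n):
    """Random binary tree with positive lengths; returns (labels, D)."""
    labels = [f"t{i}" for i in range(n)]
    # adjacency of a random tree built by sequential attachment
    edges = {}
    nodes = [0, 1]
    edges[(0, 1)] = float(rng.uniform(0.1, 2.0))
    next_internal = n  # internal node ids from n upward
    for leaf in range(2, n):
        # pick a random existing edge and subdivide it, hanging the new leaf
        (a, b) = list(edges)[int(rng.integers(0, len(edges)))]
        w = edges.pop((a, b))
        mid = next_internal
        next_internal += 1
        cut = float(rng.uniform(0.1, 0.9)) * w
        edges[(a, mid)] = cut
        edges[(mid, b)] = w - cut
        edges[(mid, leaf)] = float(rng.uniform(0.1, 2.0))
        nodes.append(leaf)
    # all-pairs path lengths via BFS over the tree graph
    adj = {}
    for (a, b), w in edges.items():
        adj.setdefault(a, []).append((b, w))
        adj.setdefault(b, []).append((a, w))
    D = np.zeros((n, n))
    for i in range(n):
        dist = {i: 0.0}
        stack = [i]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for j in range(n):
            D[i, j] = dist[j]
    return labels, D


class TestBinaryDistance:
    def test_identical_rows_distance_zero(self):
        aflp = make_aflp([[1, 0, 1], [1, 0, 1], [0, 1, 0]])
        D = phylo.binary_distance(aflp)
        assert D.iloc[0, 1] == 0.0

    def test_opposite_rows_distance_one(self):
        aflp = make_aflp([[1, 1, 0, 0], [0, 0, 1, 1], [1, 0, 1, 0]])
        D = phylo.binary_distance(aflp)
        assert D.iloc[0, 1] == 1.0

    def test_matches_per_pair_count_oracle(self, rng):
        X = rng.integers(0, 2, size=(6, 20)).astype(float)
        X[rng.random(X.shape) < 0.1] = np.nan
        aflp = make_aflp(X)
        D = phylo.binary_distance(aflp)
        for i in range(6):
            for j in range(6):
                both = ~np.isnan(X[i]) & ~np.isnan(X[j])
                want = (X[i][both] != X[j][both]).sum() / both.sum()
                assert D.iloc[i, j] == pytest.approx(want, abs=1e-12)

    def test_no_comparable_markers_is_error(self):
        X = np.array([[1.0, np.nan], [np.nan, 1.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match="comparable"):
            phylo.binary_distance(make_aflp(X))


class TestNeighborJoining:
    def test_recovers_known_four_taxon_tree(self):
        # additive matrix of ((A:1,B:2):1,(C:3,D:1))
        D = pd.DataFrame(
            [[0, 3, 5, 3], [3, 0, 6, 4], [5, 6, 0, 4], [3, 4, 4, 0]],
            index=list("ABCD"), columns=list("ABCD"), dtype=float)
        tree = phylo.neighbor_joining(D)
        d = patristic(tree)
        for a, b in itertools.combinations("ABCD", 2):
            assert d(a, b) == pytest.approx(D.loc[a, b], abs=1e-9)
        # AB|CD is the unique internal split
        assert frozenset({"A", "B"}) in phylo.bipartitions(tree)

    def test_recovers_random_additive_matrices_exactly(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 9))
            labels, D = random_additive_matrix(rng, n)
            tree = phylo.neighbor_joining(pd.DataFrame(D, index=labels, columns=labels))
            d = patristic(tree)
            for i, j in itertools.combinations(range(n), 2):
                assert d(labels[i], labels[j]) == pytest.approx(D[i, j], abs=1e-9)

    def test_star_matrix_zero_internal_lengths(self):
        D = np.full((5, 5), 2.0)
        np.fill_diagonal(D, 0.0)
        tree = phylo.neighbor_joining(D)
        internal = [
            nd.edge.length for nd in tree.preorder_node_iter()
            if nd.parent_node is not None and not nd.is_leaf()
        ]
        assert all(abs(l) < 1e-9 for l in internal)

    def test_nan_rejected(self):
        D = np.zeros((4, 4))
        D[0, 1] = D[1, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            phylo.neighbor_joining(D)


class TestBootstrap:
    def test_fixed_difference_clades_full_support(self):
        X = np.zeros((8, 30))
        X[:4] = 1.0
        rng = np.random.default_rng(1)
        noise = rng.integers(0, 2, size=(8, 10)).astype(float)
        aflp = make_aflp(np.column_stack([X, noise]))
        tree = phylo.bootstrap_support(aflp, n_reps=100, seed=2)
        target = frozenset(f"i{r}" for r in range(4))
        supports = {
            frozenset(l.taxon.label for l in nd.leaf_iter()): nd.support
            for nd in tree.preorder_node_iter()
            if nd.parent_node is not None and not nd.is_leaf()
        }
        full = {min(k, frozenset(f"i{r}" for r in range(8)) - k,
                    key=lambda s: (len(s), tuple(sorted(s)))): v for k, v in supports.items()}
        assert full[target] == 100.0

    def test_single_replicate_supports_binary(self):
        rng = np.random.default_rng(3)
        aflp = make_aflp(rng.integers(0, 2, size=(6, 25)).astype(float))
        tree = phylo.bootstrap_support(aflp, n_reps=1, seed=4)
        for nd in tree.preorder_node_iter():
            if hasattr(nd, "support"):
                assert nd.support in (0.0, 100.0)

    def test_single_informative_marker_support_near_inclusion_probability(self):
        # one marker carries the split; all others are constant.  The split's
        # support is at least the column-inclusion probability 1-(1-1/L)^L
        # (about 63%) — tie-breaking on the empty resamples can only add to it.
        L = 200
        X = np.zeros((6, L))
        X[:3, 0] = 1.0
        tree = phylo.bootstrap_support(make_aflp(X), n_reps=400, seed=5)
        target = frozenset(f"i{r}" for r in range(3))
        hit = [nd.support for nd in tree.preorder_node_iter()
               if nd.parent_node is not None and not nd.is_leaf()
               and frozenset(l.taxon.label for l in nd.leaf_iter()) in (target,)]
        incl = 100 * (1 - (1 - 1 / L) ** L)
        se = 100 * np.sqrt(0.63 * 0.37 / 400)
        assert hit and hit[0] >= incl - 4 * se

    def test_supports_invariant_to_taxon_order(self, rng):
        X = rng.integers(0, 2, size=(7, 40)).astype(float)
        aflp = make_aflp(X)
        t1 = phylo.bootstrap_support(aflp, n_reps=50, seed=9)
        perm = rng.permutation(aflp.individuals)
        t2 = phylo.bootstrap_support(aflp.subset(sample_ids=perm), n_reps=50, seed=9)
        def support_map(t):
            out = {}
            all_taxa = frozenset(l.taxon.label for l in t.leaf_node_iter())
            for nd in t.preorder_node_iter():
                if nd.parent_node is None or nd.is_leaf():
                    continue
                side = frozenset(l.taxon.label for l in nd.leaf_iter())
                canon = min(side, all_taxa - side, key=lambda s: (len(s), tuple(sorted(s))))
                out[canon] = nd.support
            return out
        m1, m2 = support_map(t1), support_map(t2)
        assert set(m1) == set(m2)


def fitch_exhaustive_min(tree, states):
    """Minimal changes by brute force over all internal-state assignments."""
    internals = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    best = np.inf
    for assign in itertools.product((0, 1), repeat=len(internals)):
        amap = dict(zip((id(n) for n in internals), assign))
        changes = 0
        ok = True
        for nd in tree.preorder_node_iter():
            if nd.parent_node is None:
                continue
            ps = amap[id(nd.parent_node)]
            if nd.is_leaf():
                v = states.get(nd.taxon.label, np.nan)
                if pd.isna(v):
                    continue
                cs = int(v)
            else:
                cs = amap[id(nd)]
            changes += int(cs != ps)
        best = min(best, changes)
    return int(best)


class TestFitch:
    def test_single_tip_trait_one_change(self):
        tree = dendropy.Tree.get(data="((A:1,B:1):1,(C:1,D:1):1);", schema="newick")
        traits = pd.DataFrame({"x": [1, 0, 0, 0]}, index=list("ABCD"))
        (rec,) = phylo.fitch_map(tree, traits)
        assert rec.n_changes == 1
        assert rec.change_edges[0][1] == "A"

    def test_uniform_trait_zero_changes(self):
        tree = dendropy.Tree.get(data="((A:1,B:1):1,(C:1,D:1):1);", schema="newick")
        traits = pd.DataFrame({"x": [1, 1, 1, 1]}, index=list("ABCD"))
        (rec,) = phylo.fitch_map(tree, traits)
        assert rec.n_changes == 0

    def test_unknown_everywhere_skipped(self):
        tree = dendropy.Tree.get(data="((A:1,B:1):1,(C:1,D:1):1);", schema="newick")
        traits = pd.DataFrame({"x": [np.nan] * 4}, index=list("ABCD"))
        (rec,) = phylo.fitch_map(tree, traits)
        assert rec.skipped

    def test_matches_exhaustive_minimization(self, rng):
        for rep in range(20):
            n = int(rng.integers(4, 9))
            labels, D = random_additive_matrix(rng, n)
            tree = phylo.neighbor_joining(pd.DataFrame(D, index=labels, columns=labels))
            tree.is_rooted = True
            states = pd.Series(rng.integers(0, 2, size=n).astype(float), index=labels)
            if rng.random() < 0.3:
                states.iloc[0] = np.nan
            traits = pd.DataFrame({"x": states})
            (rec,) = phylo.fitch_map(tree, traits)
            assert rec.n_changes == fitch_exhaustive_min(tree, states)

    def test_thermal_traits_single_gain_on_canadensis(self):
        tree = dendropy.Tree.get(data=datasets.backbone_newick(), schema="newick")
        traits = datasets.species_traits().drop(index="appalachiensis")
        recs = {r.trait: r for r in phylo.fitch_map(tree, traits, outgroup="garamas")}
        for trait in ("diapause", "univoltinism"):
            rec = recs[trait]
            assert rec.n_changes == 1
            assert rec.change_edges == [("{canadensis,glaucus}", "canadensis")]

    def test_female_dimorphism_unique_gain_in_glaucus(self):
        tree = dendropy.Tree.get(data=datasets.backbone_newick(), schema="newick")
        traits = datasets.species_traits().drop(index="appalachiensis")
        recs = {r.trait: r for r in phylo.fitch_map(tree, traits, outgroup="garamas")}
        assert recs["female_dimorphism"].n_changes == 1
        assert recs["female_dimorphism"].change_edges[0][1] == "glaucus"
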
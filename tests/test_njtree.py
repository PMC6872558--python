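"""Neighbor-joining, bootstrap support, and monophyly tests."""

import numpy as np
import pytest

from barcodeval.njtree import bootstrap_support, monophyly, nj, reroot
from barcodeval.seqdata import InputError

from .conftest import make_alignment, make_dm


def random_additive_tree(rng, n_taxa):
    """Random binary tree with positive branch lengths; returns
    (splits, leaf-distance matrix, labels) computed by path additivity —
    an oracle independent of the NJ code."""
    labels = [f"t{i:02d}" for i in range(n_taxa)]
    # start from 3-leaf star, attach remaining leaves to random edges;
    # adjacency: node -> {neighbor: length}
    adj = {"r": {}}
    edges = []

    def add_edge(a, b, ln):
        adj.setdefault(a, {})[b] = ln
        adj.setdefault(b, {})[a] = ln
        edges.append((a, b))

    for i in range(3):
        add_edge("r", labels[i], float(rng.uniform(0.1, 1.0)))
    internal = 0
    for i in range(3, n_taxa):
        a, b = edges[rng.integers(len(edges))]
        ln = adj[a].pop(b)
        adj[b].pop(a)
        edges.remove((a, b))
        mid = f"x{internal}"
        internal += 1
        u = float(rng.uniform(0.2, 0.8))
        add_edge(a, mid, ln * u)
        add_edge(mid, b, ln * (1 - u))
        add_edge(mid, labels[i], float(rng.uniform(0.1, 1.0)))

    # all-pairs leaf distances by DFS
    dist = np.zeros((n_taxa, n_taxa))
    for i, src in enumerate(labels):
        seen = {src: 0.0}
        stack = [src]
        while stack:
            cur = stack.pop()
            for nxt, ln in adj[cur].items():
                if nxt not in seen:
                    seen[nxt] = seen[cur] + ln
                    stack.append(nxt)
        for j, dst in enumerate(labels):
            dist[i, j] = seen[dst]

    # non-trivial splits by cutting each internal edge
    splits = set()
    leafset = set(labels)
    for a, b in edges:
        comp = {b}
        stack = [b]
        while stack:
            cur = stack.pop()
            for nxt in adj[cur]:
                if nxt != a and nxt not in comp:
                    comp.add(nxt)
                    stack.append(nxt)
        side = frozenset(l for l in comp if l in leafset)
        if 2 <= len(side) <= n_taxa - 2:
            anchor = min(labels)
            splits.add(side if anchor not in side else
                       frozenset(leafset - side))
    return splits, dist, labels


class TestNJ:
    def test_worked_four_taxon_example(self):
        # additive matrix of the tree ((A:1,B:2):1,C:3,D:4)
        labels = ["A", "B", "C", "D"]
        v = np.array([
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ], dtype=float)
        tree = nj(make_dm(v, ["a", "b", "c", "d"], labels=labels))
        splits = tree.splits()
        assert frozenset({"C", "D"}) in splits or \
            frozenset({"A", "B"}) in splits
        lengths = {}

        def collect(node, parent_internal):
            for c in node.children:
                if c.is_leaf:
                    lengths[c.name] = c.length
                else:
                    lengths["internal"] = c.length
                    collect(c, True)

        collect(tree.root, False)
        assert lengths == pytest.approx(
            {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0, "internal": 1.0}
        )

    def test_three_taxa_closed_form(self):
        v = np.array([[0, 0.2, 0.3], [0.2, 0, 0.5], [0.3, 0.5, 0]])
        tree = nj(make_dm(v, ["a", "b", "c"], labels=["a", "b", "c"]))
        got = {l.name: l.length for l in tree.root.leaves()}
        assert got["a"] == pytest.approx(0.5 * (0.2 + 0.3 - 0.5))
        assert got["b"] == pytest.approx(0.5 * (0.2 + 0.5 - 0.3))
        assert got["c"] == pytest.approx(0.5 * (0.3 + 0.5 - 0.2))

    def test_fewer_than_three_taxa_rejected(self):
        v = np.array([[0, 0.1], [0.1, 0]])
        with pytest.raises(InputError):
            nj(make_dm(v, ["a", "b"]))

    def test_undefined_entries_rejected(self):
        v = np.array([[0, np.nan, 0.1], [np.nan, 0, 0.1], [0.1, 0.1, 0]])
        with pytest.raises(InputError, match="undefined"):
            nj(make_dm(v, ["a", "b", "c"]))

    def test_recovers_random_additive_trees(self, rng):
        """Topology and patristic distances within 1e-9 on additive input."""
        for _ in range(100):
            n = int(rng.integers(4, 13))
            true_splits, dist, labels = random_additive_tree(rng, n)
            tree = nj(make_dm(dist, [f"sp{i}" for i in range(n)],
                              labels=labels))
            assert set(tree.splits()) == true_splits
            names, got = tree.leaf_distances()
            order = [names.index(l) for l in labels]
            np.testing.assert_allclose(
                got[np.ix_(order, order)], dist, atol=1e-9
            )

    def test_agrees_with_scikit_bio_on_random_matrices(self, rng):
        """Independent implementation cross-check: same unrooted topology."""
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sknj

        for _ in range(20):
            n = int(rng.integers(5, 10))
            v = rng.random((n, n))
            v = (v + v.T) / 2
            np.fill_diagonal(v, 0.0)
            labels = [f"t{i:02d}" for i in range(n)]
            mine = nj(make_dm(v, [f"sp{i}" for i in range(n)], labels=labels))
            ref = sknj(SkDM(v, ids=labels))
            anchor = min(labels)
            leafset = frozenset(labels)
            ref_splits = set()
            for s in ref.subsets():
                side = frozenset(s)
                if 2 <= len(side) <= n - 2:
                    ref_splits.add(side if anchor not in side
                                   else leafset - side)
            assert set(mine.splits()) == ref_splits

    def test_input_order_invariance(self, rng):
        _, dist, labels = random_additive_tree(rng, 8)
        dm = make_dm(dist, [f"sp{i}" for i in range(8)], labels=labels)
        perm = list(rng.permutation(8))
        dm2 = dm.submatrix(perm)
        assert nj(dm).newick() == nj(dm2).newick()


class TestBootstrap:
    def two_group_alignment(self):
        # two 3-sequence groups separated by 20 diagnostic columns
        base_x = "A" * 40 + "C" * 40
        base_y = "A" * 20 + "G" * 20 + "C" * 40
        a = base_x
        b = base_x[:-1] + "T"
        c = base_x[:39] + "G" + base_x[40:]
        d = base_y
        e = base_y[:-1] + "T"
        f = base_y[:39] + "A" + base_y[40:]
        return make_alignment(
            [a, b, c, d, e, f],
            species=["x", "x", "x", "y", "y", "y"],
            ids=["x1", "x2", "x3", "y1", "y2", "y3"],
        )

    def test_central_split_near_certain(self):
        tree = bootstrap_support(self.two_group_alignment(),
                                 replicates=100, seed=5)
        split = frozenset({"y1", "y2", "y3"})
        assert split in tree.splits()
        assert tree.splits()[split].support >= 99.0

    def test_single_replicate_supports_binary(self):
        tree = bootstrap_support(self.two_group_alignment(),
                                 replicates=1, seed=2)
        sup = [n.support for n in tree.splits().values()]
        assert sup and all(s in (0.0, 100.0) for s in sup)

    def test_fixed_seed_reproducible(self):
        aln = self.two_group_alignment()
        t1 = bootstrap_support(aln, replicates=25, seed=7)
        t2 = bootstrap_support(aln, replicates=25, seed=7)
        assert t1.newick() == t2.newick()

    def test_leaf_order_invariance(self, rng):
        aln = self.two_group_alignment()
        perm = list(rng.permutation(6))
        shuffled = make_alignment(
            [aln.records[i].residues for i in perm],
            species=[aln.records[i].species for i in perm],
            ids=[aln.records[i].sample_id for i in perm],
        )
        t1 = bootstrap_support(aln, replicates=25, seed=11)
        t2 = bootstrap_support(shuffled, replicates=25, seed=11)
        assert t1.newick() == t2.newick()


class TestMonophyly:
    def tree_of(self, seqs, species, ids):
        from barcodeval.k2p import k2p_matrix

        aln = make_alignment(seqs, species=species, ids=ids)
        return nj(k2p_matrix(aln)), dict(zip(ids, species))

    def test_clean_groups_are_monophyletic(self):
        tree, smap = self.tree_of(
            ["AAAAACCCCC", "AAAAACCCCT", "GGAAACCCCC", "GGAAACCCCT"],
            ["A", "A", "B", "B"], ["a1", "a2", "b1", "b2"],
        )
        calls = {c.species: c for c in monophyly(tree, smap)}
        assert calls["A"].monophyletic and calls["B"].monophyletic
        assert not calls["A"].trivial

    def test_interleaved_groups_are_not(self):
        # a1 pairs with b1 and a2 with b2 by sequence
        tree, smap = self.tree_of(
            ["AAAAACCCCC", "GGAAACCCCC", "AAAAACCCCT", "GGAAACCCCT"],
            ["A", "A", "B", "B"], ["a1", "a2", "b1", "b2"],
        )
        calls = {c.species: c for c in monophyly(tree, smap)}
        assert not calls["A"].monophyletic
        assert not calls["B"].monophyletic

    def test_singleton_trivially_monophyletic(self):
        tree, smap = self.tree_of(
            ["AAAAACCCCC", "AAAAACCCCT", "GGGAACCCCC"],
            ["A", "A", "B"], ["a1", "a2", "b1"],
        )
        calls = {c.species: c for c in monophyly(tree, smap)}
        assert calls["B"].monophyletic and calls["B"].trivial

    def test_unknown_leaf_raises(self):
        tree, smap = self.tree_of(
            ["AAAAACCCCC", "AAAAACCCCT", "GGGAACCCCC"],
            ["A", "A", "B"], ["a1", "a2", "b1"],
        )
        with pytest.raises(KeyError):
            monophyly(tree, {"zz": "A", **smap})


class TestNewickAndReroot:
    def test_newick_parseable_by_dendropy(self, rng):
        import dendropy

        _, dist, labels = random_additive_tree(rng, 7)
        tree = nj(make_dm(dist, [f"sp{i}" for i in range(7)], labels=labels))
        parsed = dendropy.Tree.get(data=tree.newick(), schema="newick",
                                   preserve_underscores=True)
        assert sorted(t.label for t in parsed.taxon_namespace) == \
            sorted(labels)

    def test_reroot_preserves_leaves_and_distances(self, rng):
        _, dist, labels = random_additive_tree(rng, 6)
        tree = nj(make_dm(dist, [f"sp{i}" for i in range(6)], labels=labels))
        rerooted = reroot(tree, labels[0])
        assert rerooted.leaf_names() == tree.leaf_names()
        n1, d1 = tree.leaf_distances()
        n2, d2 = rerooted.leaf_distances()
        order = [n2.index(l) for l in n1]
        np.testing.assert_allclose(d2[np.ix_(order, order)], d1, atol=1e-9)
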
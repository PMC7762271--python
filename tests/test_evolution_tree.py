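"""Neighbor joining: worked example, consistency on additive matrices,
cross-check against scikit-bio, bootstrap supports and clade transfer."""

import io

import numpy as np
import pytest

from genefamkit.evolution import assign_clades, bootstrap_support, nj_tree

WORKED = np.array(
    [
        [0, 5, 9, 9],
        [5, 0, 10, 10],
        [9, 10, 0, 8],
        [9, 10, 8, 0],
    ],
    dtype=float,
)


def random_additive_case(seed, n_leaves=8):
    """Random unrooted binary tree -> (distance matrix, true bipartitions)."""
    import networkx as nx

    rng = np.random.default_rng(seed)
    g = nx.Graph()
    active = [f"L{i}" for i in range(n_leaves)]
    counter = 0
    while len(active) > 3:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        node = f"I{counter}"
        counter += 1
        g.add_edge(active[i], node, weight=rng.uniform(0.1, 1.0))
        g.add_edge(active[j], node, weight=rng.uniform(0.1, 1.0))
        active = [a for k, a in enumerate(active) if k not in (i, j)] + [node]
    hub = "HUB"
    for a in active:
        g.add_edge(a, hub, weight=rng.uniform(0.1, 1.0))
    leaves = [f"L{i}" for i in range(n_leaves)]
    dist = np.zeros((n_leaves, n_leaves))
    import networkx as nx

    lengths = dict(nx.all_pairs_dijkstra_path_length(g))
    for a in range(n_leaves):
        for b in range(n_leaves):
            dist[a, b] = lengths[leaves[a]][leaves[b]]
    # true bipartitions from internal edges
    anchor = min(leaves)
    biparts = set()
    for u, v in list(g.edges):
        h = g.copy()
        h.remove_edge(u, v)
        comp = nx.node_connected_component(h, u)
        side = frozenset(l for l in leaves if l in comp)
        if anchor in side:
            side = frozenset(set(leaves) - side)
        if 2 <= len(side) <= n_leaves - 2:
            biparts.add(side)
    return dist, leaves, biparts


class TestNjTree:
    def test_worked_four_taxon_example(self):
        tree = nj_tree(WORKED, ["A", "B", "C", "D"])
        assert tree.bipartitions() == {frozenset({"C", "D"})}
        lengths = {l.name: l.length for l in tree.root.leaves()}
        assert lengths == pytest.approx({"A": 2.0, "B": 3.0, "C": 4.0, "D": 4.0})
        internal = [c for c in tree.root.children if not c.is_leaf]
        assert len(internal) == 1 and internal[0].length == pytest.approx(3.0)

    def test_three_taxa_closed_form(self):
        tree = nj_tree(np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float),
                       ["x", "y", "z"])
        lengths = {l.name: l.length for l in tree.root.leaves()}
        assert lengths == pytest.approx({"x": 1.0, "y": 2.0, "z": 3.0})
        assert len(tree.root.children) == 3  # root trifurcation

    def test_topology_recovery_on_random_additive_matrices(self):
        hits = 0
        for seed in range(50):
            dist, leaves, true_biparts = random_additive_case(seed)
            tree = nj_tree(dist, leaves)
            hits += tree.bipartitions() == true_biparts
        assert hits == 50

    def test_agrees_with_scikit_bio_nj(self):
        import skbio

        dist, leaves, _ = random_additive_case(seed=1234)
        dist = (dist + dist.T) / 2.0  # symmetrise float summation noise
        ours = skbio.TreeNode.read(io.StringIO(nj_tree(dist, leaves).newick()))
        theirs = skbio.tree.nj(skbio.DistanceMatrix(dist, ids=leaves))
        assert ours.compare_rfd(theirs) == 0.0

    def test_asymmetric_matrix_rejected(self):
        bad = WORKED.copy()
        bad[0, 1] = 7.0
        with pytest.raises(ValueError):
            nj_tree(bad, list("ABCD"))

    def test_branch_lengths_never_negative(self):
        rng = np.random.default_rng(77)
        for _ in range(20):
            n = 6
            noise = rng.uniform(0, 1, size=(n, n))
            dist = (noise + noise.T) / 2
            np.fill_diagonal(dist, 0)
            tree = nj_tree(dist, [f"t{i}" for i in range(n)])

            def lengths(node):
                out = [node.length]
                for c in node.children:
                    out.extend(lengths(c))
                return out

            assert all(l >= 0 for c in tree.root.children for l in lengths(c))


def two_cluster_sequences(noise=0.05, n_per=4, length=60, seed=0):
    rng = np.random.default_rng(seed)
    alpha = "ACDEFGHIKLMNPQRSTVWY"
    cons_a = "".join(alpha[i] for i in rng.integers(0, 20, length))
    cons_b = "".join(alpha[i] for i in rng.integers(0, 20, length))
    seqs = {}
    for tag, cons in (("a", cons_a), ("b", cons_b)):
        for k in range(n_per):
            s = list(cons)
            for pos in range(length):
                if rng.random() < noise:
                    s[pos] = alpha[rng.integers(20)]
            seqs[f"{tag}{k}"] = "".join(s)
    return seqs


class TestBootstrap:
    def test_planted_split_gets_high_support(self):
        seqs = two_cluster_sequences()
        tree = bootstrap_support(seqs, n_replicates=100, seed=3)
        split = frozenset({"b0", "b1", "b2", "b3"})
        supports = {}
        for node in tree._internal_nodes():
            side = {l.name for l in node.leaves()}
            if side in ({"a0", "a1", "a2", "a3"}, {"b0", "b1", "b2", "b3"}):
                supports[frozenset(side)] = node.support
        assert any(s is not None and s >= 95 for s in supports.values())

    def test_zero_replicates_gives_tree_without_supports(self):
        tree = bootstrap_support(two_cluster_sequences(), n_replicates=0, seed=3)
        assert all(n.support is None for n in tree._internal_nodes())

    def test_same_seed_identical_supports(self):
        seqs = two_cluster_sequences()
        t1 = bootstrap_support(seqs, n_replicates=50, seed=8)
        t2 = bootstrap_support(seqs, n_replicates=50, seed=8)
        assert t1.newick() == t2.newick()


class TestAssignClades:
    def test_sister_reference_label_transfers(self):
        seqs = two_cluster_sequences()
        tree = bootstrap_support(seqs, n_replicates=0, seed=0)
        clades = assign_clades(
            tree, {"a0": "alpha", "b0": "beta"}
        )
        assert clades["a1"] == "alpha" and clades["b3"] == "beta"

    def test_equidistant_tie_breaks_alphabetically(self):
        tree = nj_tree(np.array([[0, 2, 2], [2, 0, 2], [2, 2, 0]], float),
                       ["query", "refA", "refB"])
        clades = assign_clades(tree, {"refA": "B_clade", "refB": "A_clade"})
        assert clades["query"] == "A_clade"

    def test_planted_three_clade_family_fully_recovered(self):
        rng = np.random.default_rng(12)
        alpha = "ACDEFGHIKLMNPQRSTVWY"
        seqs, labels = {}, {}
        for tag in ("x", "y", "z"):
            cons = "".join(alpha[i] for i in rng.integers(0, 20, 50))
            for k in range(4):
                s = [c if rng.random() > 0.05 else alpha[rng.integers(20)]
                     for c in cons]
                seqs[f"{tag}{k}"] = "".join(s)
            labels[f"{tag}0"] = tag
        tree = bootstrap_support(seqs, n_replicates=0, seed=0)
        clades = assign_clades(tree, labels)
        assert all(clades[leaf] == leaf[0] for leaf in clades)

    def test_no_references_rejected(self):
        tree = nj_tree(WORKED, list("ABCD"))
        with pytest.raises(ValueError):
            assign_clades(tree, {})
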
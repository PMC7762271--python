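"""Neighbor-joining phylogeny with bootstrap supports and clade transfer.

Saitou-Nei NJ joins the pair minimising the Q criterion; the method is
consistent on additive distance matrices, so exact topologies are
recoverable in tests.  Ties break by the smallest (i, j) index pair;
negative branch lengths are clamped to zero with the deficit moved to the
sister branch.  The finished tree is unrooted with a root trifurcation.
Bootstrap supports resample alignment columns with replacement and report
the percentage of replicate trees containing each internal bipartition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np


@dataclass
class TreeNode:
    name: str = ""
    length: float = 0.0  # branch length to parent
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def newick(self, with_length: bool = True) -> str:
        if self.is_leaf:
            core = self.name
        else:
            inner = ",".join(c.newick(with_length) for c in self.children)
            label = "" if self.support is None else f"{self.support:g}"
            core = f"({inner}){label}"
        if with_length:
            return f"{core}:{self.length:.6g}"
        return core


@dataclass
class PhyloTree:
    """Unrooted NJ tree (root trifurcation) with optional clade labels."""

    root: TreeNode
    clades: dict[str, str] = field(default_factory=dict)

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.root.leaves()]

    def newick(self) -> str:
        inner = ",".join(c.newick() for c in self.root.children)
        return f"({inner});"

    def _internal_nodes(self) -> list[TreeNode]:
        out = []

        def visit(node: TreeNode) -> None:
            for c in node.children:
                if not c.is_leaf:
                    out.append(c)
                visit(c)

        visit(self.root)
        return out

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial leaf bipartitions, each represented by the side not
        containing the lexicographically smallest leaf."""
        all_leaves = set(self.leaf_names())
        anchor = min(all_leaves)
        out: set[frozenset[str]] = set()
        for node in self._internal_nodes():
            side = {l.name for l in node.leaves()}
            if anchor in side:
                side = all_leaves - side
            if 2 <= len(side) <= len(all_leaves) - 2:
                out.add(frozenset(side))
        return out

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        counter = [0]

        def visit(node: TreeNode, ident: str) -> None:
            for c in node.children:
                if c.is_leaf:
                    cid = c.name
                else:
                    counter[0] += 1
                    cid = f"__internal_{counter[0]}"
                g.add_edge(ident, cid, weight=max(c.length, 0.0))
                visit(c, cid)

        g.add_node("__root")
        visit(self.root, "__root")
        return g

    def patristic_distances(self) -> dict[str, dict[str, float]]:
        g = self.to_graph()
        leaves = self.leaf_names()
        out: dict[str, dict[str, float]] = {}
        for leaf in leaves:
            lengths = nx.single_source_dijkstra_path_length(g, leaf)
            out[leaf] = {other: lengths[other] for other in leaves}
        return out


def _check_distance_matrix(dist: np.ndarray, n_labels: int) -> np.ndarray:
    D = np.asarray(dist, dtype=float).copy()
    if D.ndim != 2 or D.shape[0] != D.shape[1] or D.shape[0] != n_labels:
        raise ValueError("distance matrix shape must match labels")
    if D.shape[0] < 3:
        raise ValueError("need at least 3 taxa")
    if not np.isfinite(D).all():
        raise ValueError("distances must be finite")
    if not np.allclose(D, D.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    np.fill_diagonal(D, 0.0)
    return D


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    """Clamp negative branch lengths to 0, moving the deficit to the sister."""
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def nj_tree(dist, labels: list[str]) -> PhyloTree:
    """Saitou-Nei neighbor joining on a symmetric distance matrix."""
    D = _check_distance_matrix(dist, len(labels))
    nodes: list[TreeNode] = [TreeNode(name=l) for l in labels]

    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        Q = (n - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(Q.argmin())  # row-major: smallest (i, j) on ties
        i, j = divmod(flat, n)
        if i > j:
            i, j = j, i
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = D[i, j] - li
        li, lj = _clamp_pair(li, lj)
        child_i, child_j = nodes[i], nodes[j]
        child_i.length, child_j.length = li, lj
        parent = TreeNode(children=[child_i, child_j])
        d_new = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        D = np.vstack([
            np.hstack([D[np.ix_(keep, keep)], d_new[keep, None]]),
            np.hstack([d_new[keep], [0.0]]),
        ])
        nodes = [nodes[k] for k in keep] + [parent]

    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    lengths = [
        0.5 * (d01 + d02 - d12),
        0.5 * (d01 + d12 - d02),
        0.5 * (d02 + d12 - d01),
    ]
    for node, length in zip(nodes, lengths):
        node.length = max(length, 0.0)
    return PhyloTree(root=TreeNode(children=nodes))


def p_distance_matrix(sequences: list[str]) -> np.ndarray:
    """Pairwise proportion of differing columns for equal-length sequences."""
    length = len(sequences[0])
    if any(len(s) != length for s in sequences):
        raise ValueError("sequences must have equal lengths")
    mat = np.array([list(s) for s in sequences])
    diff = (mat[:, None, :] != mat[None, :, :]).mean(axis=2)
    np.fill_diagonal(diff, 0.0)
    return diff


def bootstrap_support(
    sequences: dict[str, str],
    n_replicates: int = 1000,
    seed: int = 0,
) -> PhyloTree:
    """NJ tree on p-distances with column-resampling bootstrap supports.

    Replicate RNG streams derive from (seed, replicate index) so results
    are reproducible regardless of execution order.
    """
    if len(sequences) < 4:
        raise ValueError("need at least 4 sequences")
    labels = list(sequences)
    mat = np.array([list(sequences[l]) for l in labels])
    length = mat.shape[1]
    base = nj_tree(p_distance_matrix(["".join(row) for row in mat]), labels)
    if n_replicates == 0:
        return base

    counts: dict[frozenset[str], int] = {}
    for rep in range(n_replicates):
        rng = np.random.default_rng([seed, rep])
        cols = rng.integers(0, length, size=length)
        sub = mat[:, cols]
        diff = (sub[:, None, :] != sub[None, :, :]).mean(axis=2)
        np.fill_diagonal(diff, 0.0)
        tree = nj_tree(diff, labels)
        for bp in tree.bipartitions():
            counts[bp] = counts.get(bp, 0) + 1

    all_leaves = set(labels)
    anchor = min(all_leaves)
    for node in base._internal_nodes():
        side = {l.name for l in node.leaves()}
        if anchor in side:
            side = all_leaves - side
        if 2 <= len(side) <= len(all_leaves) - 2:
            node.support = 100.0 * counts.get(frozenset(side), 0) / n_replicates
    return base


def assign_clades(tree: PhyloTree, reference_labels: dict[str, str]) -> dict[str, str]:
    """Assign each unlabeled leaf the clade of its nearest labelled leaf by
    patristic distance (ties by alphabetical clade id)."""
    if not reference_labels:
        raise ValueError("no reference labels given")
    leaves = tree.leaf_names()
    missing = set(reference_labels) - set(leaves)
    if missing:
        raise ValueError(f"reference leaves not in tree: {sorted(missing)}")
    dists = tree.patristic_distances()
    out: dict[str, str] = {}
    for leaf in leaves:
        if leaf in reference_labels:
            continue
        best = min(
            ((dists[leaf][ref], clade) for ref, clade in reference_labels.items()),
            key=lambda t: (t[0], t[1]),
        )
        out[leaf] = best[1]
    tree.clades = {**reference_labels, **out}
    return out
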
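"""Robinson–Foulds distances, random SPR neighbours, and the
starting-tree-bias permutation test.

The bias test asks whether partitioning schemes inferred from a set of
starting trees pull the subsequently estimated ML trees towards those
starting trees.  The observed statistic is the sum of RF distances over
the matched (starting tree, ML tree) pairs; the null distribution comes
from re-computing the statistic after randomly shuffling the list of ML
trees, and the one-tailed p-value is the rank position of the observed
value in the null (add-one convention, so p is in [1/(B+1), 1]).
A standardised effect size (observed minus null mean, over null SD) is
reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np
from dendropy.calculate import treecompare

__all__ = [
    "BiasTestResult",
    "rf_distance",
    "random_spr_neighbor",
    "starting_tree_bias_test",
]


def _as_unrooted_pair(t1: dendropy.Tree, t2: dendropy.Tree):
    tns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(
        data=t1.as_string(schema="newick"), schema="newick",
        taxon_namespace=tns, preserve_underscores=True,
    )
    b = dendropy.Tree.get(
        data=t2.as_string(schema="newick"), schema="newick",
        taxon_namespace=tns, preserve_underscores=True,
    )
    a.is_rooted = False
    b.is_rooted = False
    return a, b


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Unrooted Robinson–Foulds distance: size of the symmetric difference
    of the two trees' non-trivial bipartition sets."""
    leaves1 = {lf.taxon.label for lf in t1.leaf_node_iter()}
    leaves2 = {lf.taxon.label for lf in t2.leaf_node_iter()}
    if leaves1 != leaves2:
        raise ValueError(
            f"trees have different leaf sets: {sorted(leaves1 ^ leaves2)}"
        )
    a, b = _as_unrooted_pair(t1, t2)
    a.encode_bipartitions()
    b.encode_bipartitions()
    return int(treecompare.symmetric_difference(a, b))


# ---------------------------------------------------------------------------
# SPR neighbours (graph surgery on the unrooted tree)


def _tree_to_graph(tree: dendropy.Tree):
    adj: dict[int, dict[int, float]] = {}
    labels: dict[int, str] = {}
    ids: dict[int, int] = {}
    for nd in tree.preorder_node_iter():
        i = ids.setdefault(id(nd), len(ids))
        adj.setdefault(i, {})
        if nd.is_leaf():
            labels[i] = nd.taxon.label
        if nd.parent_node is not None:
            p = ids[id(nd.parent_node)]
            ln = nd.edge.length if nd.edge.length is not None else 1.0
            adj[i][p] = adj[p][i] = float(ln)
    _suppress_degree2(adj, labels)
    return adj, labels


def _suppress_degree2(adj, labels, keep=()) -> None:
    # a rooted binary tree's root is a degree-2 vertex of the unrooted graph
    for node in [
        n for n in list(adj) if len(adj[n]) == 2 and n not in labels and n not in keep
    ]:
        (a, la), (b, lb) = adj[node].items()
        del adj[a][node]
        del adj[b][node]
        adj[a][b] = adj[b][a] = la + lb
        del adj[node]


def _graph_to_tree(adj, labels) -> dendropy.Tree:
    tns = dendropy.TaxonNamespace()
    internal = [n for n in adj if n not in labels]
    root = internal[0] if internal else next(iter(adj))
    tree = dendropy.Tree(taxon_namespace=tns)
    nodes = {root: tree.seed_node}
    stack = [(root, None)]
    while stack:
        cur, parent = stack.pop()
        for nb, ln in adj[cur].items():
            if nb == parent:
                continue
            child = dendropy.Node()
            if nb in labels:
                child.taxon = tns.new_taxon(label=labels[nb])
            nodes[cur].add_child(child)
            child.edge.length = ln
            nodes[nb] = child
            stack.append((nb, cur))
    tree.is_rooted = False
    return tree


def _component(adj, start, blocked_edge):
    seen = {start}
    stack = [start]
    while stack:
        cur = stack.pop()
        for nb in adj[cur]:
            if (cur, nb) == blocked_edge or (nb, cur) == blocked_edge:
                continue
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return seen


def random_spr_neighbor(
    tree: dendropy.Tree,
    rng: np.random.Generator | int | None = None,
    max_tries: int = 100,
) -> dendropy.Tree:
    """A uniformly drawn subtree-prune-and-regraft neighbour.

    The pruned branch keeps its length; the branch lengths of the vertex
    removed by the prune are summed through; the regraft edge is split at
    its midpoint.  Moves that reproduce the input topology are re-drawn;
    after ``max_tries`` failures an error is raised.
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    n_leaves = sum(1 for _ in tree.leaf_node_iter())
    if n_leaves < 4:
        raise ValueError("SPR needs at least four taxa")
    adj0, labels = _tree_to_graph(tree)
    for _ in range(max_tries):
        adj = {k: dict(v) for k, v in adj0.items()}
        edges = [(u, v) for u in adj for v in adj[u] if u < v]
        u, v = edges[rng.integers(len(edges))]
        if rng.random() < 0.5:
            u, v = v, u
        # prune the v-side component, leaving the rest attached at u
        rest = _component(adj, u, (u, v))
        if len(rest) < 3:
            continue
        prune_len = adj[u][v]
        del adj[u][v]
        del adj[v][u]
        # the cut vertex v keeps the pruned edge hanging from it; only the
        # degree-2 vertex left behind on the rest side is smoothed out
        _suppress_degree2(adj, labels, keep=(v,))
        rest_edges = [
            (x, y) for x in adj for y in adj[x]
            if x < y and x in rest and y in rest
        ]
        if not rest_edges:
            continue
        x, y = rest_edges[rng.integers(len(rest_edges))]
        w = max(adj) + 1
        half = adj[x][y] / 2.0
        del adj[x][y]
        del adj[y][x]
        adj[w] = {}
        adj[w][x] = adj.setdefault(x, {})[w] = half
        adj[w][y] = adj.setdefault(y, {})[w] = half
        adj[w][v] = adj[v][w] = prune_len
        cand = _graph_to_tree(adj, labels)
        if rf_distance(tree, cand) > 0:
            return cand
    raise RuntimeError("could not find a topologically distinct SPR neighbour")


# ---------------------------------------------------------------------------
# Permutation test


@dataclass
class BiasTestResult:
    """Outcome of the starting-tree-bias permutation test."""

    observed: int
    null_distribution: np.ndarray
    p_value: float
    effect_size: float
    n_perm: int


def rf_matrix(
    start_trees: Sequence[dendropy.Tree], ml_trees: Sequence[dendropy.Tree]
) -> np.ndarray:
    """All pairwise RF distances between the two tree lists."""
    n = len(start_trees)
    M = np.zeros((n, len(ml_trees)), dtype=int)
    for i, s in enumerate(start_trees):
        for k, m in enumerate(ml_trees):
            M[i, k] = rf_distance(s, m)
    return M


def starting_tree_bias_test(
    start_trees: Sequence[dendropy.Tree],
    ml_trees: Sequence[dendropy.Tree],
    n_perm: int = 999,
    rng: np.random.Generator | int | None = None,
) -> BiasTestResult:
    """Permutation test for starting-tree bias.

    observed = sum_i RF(start_i, ml_i); the null shuffles the ML-tree list;
    p = (1 + #{null <= observed}) / (n_perm + 1).  Starting trees that
    bias the inference give an observed statistic in the lower tail.
    """
    if len(start_trees) != len(ml_trees):
        raise ValueError("tree lists must have equal length")
    n = len(start_trees)
    if n < 2:
        raise ValueError("need at least two tree pairs")
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    M = rf_matrix(start_trees, ml_trees)
    observed = int(np.trace(M))
    idx = np.arange(n)
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(n)
        null[b] = M[idx, perm].sum()
    p = (1.0 + float((null <= observed).sum())) / (n_perm + 1.0)
    sd = float(null.std(ddof=1))
    effect = (observed - float(null.mean())) / sd if sd > 0 else 0.0
    return BiasTestResult(
        observed=observed, null_distribution=null, p_value=p,
        effect_size=effect, n_perm=n_perm,
    )
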
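"""Synthetic data: Yule trees, sequence evolution, two-block datasets.

The validation design this module reproduces: draw a pure-birth (Yule)
tree, scale it to a shallow depth (0.1 expected substitutions root to
tip) and simulate a 1,000 bp Jukes–Cantor alignment; rescale the same
topology ten-fold deeper (depth 1.0) and simulate a second 1,000 bp
block; concatenate (2,000 bp total) and keep the per-site generating
block labels.  The partitioner's output can then be graded by *subset
purity*: the fraction of each inferred subset's sites that came from its
majority generating block, summarised at the 95% purity threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np

from .msa_io import Alignment
from .phylo_likelihood import ModelSpec, _eigen_system, model_by_name

__all__ = [
    "SimulatedDataset",
    "PurityReport",
    "yule_tree",
    "tree_depth",
    "scale_tree_depth",
    "simulate_alignment",
    "two_block_dataset",
    "subset_purity",
]

_BASES = np.array(["A", "C", "G", "T"])


@dataclass
class SimulatedDataset:
    """A concatenated multi-block alignment with its generating truth."""

    alignment: Alignment
    true_labels: np.ndarray
    trees: list[dendropy.Tree]
    params: dict = field(default_factory=dict)


def yule_tree(
    n_tips: int,
    birth: float,
    rng: np.random.Generator | int | None = None,
    label_prefix: str = "t",
) -> dendropy.Tree:
    """Rooted ultrametric pure-birth tree.

    Standard construction: starting from two lineages at the root,
    waiting times between speciations are exponential with rate
    ``birth * (current number of lineages)`` and the splitting lineage is
    chosen uniformly; after the n-th tip appears, all tips are extended
    by one more exponential waiting time so terminal branches are
    positive.
    """
    if n_tips < 2:
        raise ValueError("need at least two tips")
    if birth <= 0:
        raise ValueError("birth rate must be positive")
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node
    t = 0.0
    active: list[tuple[dendropy.Node, float]] = []
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        active.append((child, 0.0))
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (birth * k))
        idx = int(rng.integers(k))
        node, born = active.pop(idx)
        node.edge.length = t - born
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            active.append((child, t))
    t_end = t + rng.exponential(1.0 / (birth * n_tips))
    for i, (node, born) in enumerate(active):
        node.edge.length = t_end - born
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon = tns.new_taxon(label=f"{label_prefix}{i + 1}")
    tree.is_rooted = True
    return tree


def tree_depth(tree: dendropy.Tree) -> float:
    """Root-to-tip path length (max over tips)."""
    return max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())


def scale_tree_depth(tree: dendropy.Tree, target_depth: float) -> dendropy.Tree:
    """Copy of an ultrametric tree with all branches multiplied so the
    root-to-tip depth equals ``target_depth``; topology and relative
    branch-length ratios are untouched."""
    if target_depth <= 0:
        raise ValueError("target depth must be positive")
    depth = tree_depth(tree)
    if depth <= 0:
        raise ValueError("cannot scale a zero-depth tree")
    out = tree.clone(depth=1)
    factor = target_depth / depth
    for e in out.preorder_edge_iter():
        if e.length is not None:
            e.length *= factor
    return out


def simulate_alignment(
    tree: dendropy.Tree,
    length: int,
    rng: np.random.Generator | int | None = None,
    spec: ModelSpec | None = None,
    exch: np.ndarray | None = None,
    freqs: np.ndarray | None = None,
) -> Alignment:
    """Evolve site-independent nucleotide sequences along a rooted tree.

    Root states are drawn from the stationary frequencies; each branch
    applies the model's transition probabilities for its length (in
    expected substitutions per site).  Defaults to Jukes–Cantor.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    spec = spec or model_by_name("JC")
    if exch is None:
        exch = np.ones(6)
    if freqs is None:
        freqs = np.full(4, 0.25)
    freqs = np.asarray(freqs, dtype=float)
    w, A, B = _eigen_system(np.asarray(exch, dtype=float), freqs)
    states: dict[int, np.ndarray] = {}
    root = tree.seed_node
    states[id(root)] = rng.choice(4, size=length, p=freqs)
    taxa: list[str] = []
    seqs: list[str] = []
    for nd in tree.preorder_node_iter():
        if nd is root:
            pass
        else:
            t = nd.edge.length if nd.edge.length is not None else 0.0
            P = (A * np.exp(w * t)) @ B
            np.clip(P, 0.0, None, out=P)
            P /= P.sum(axis=1, keepdims=True)
            parent_states = states[id(nd.parent_node)]
            cum = P.cumsum(axis=1)[parent_states]
            u = rng.random(length)
            states[id(nd)] = (u[:, None] > cum).sum(axis=1).clip(0, 3)
        if nd.is_leaf():
            taxa.append(nd.taxon.label)
            seqs.append("".join(_BASES[states[id(nd)]]))
    return Alignment.from_sequences(taxa, seqs)


def two_block_dataset(
    rng: np.random.Generator | int | None = None,
    n_tips: int = 100,
    birth: float = 0.1,
    depths: Sequence[float] = (0.1, 1.0),
    block_length: int = 1000,
) -> SimulatedDataset:
    """One replicate of the two-block Yule/JC validation design.

    A single Yule topology is scaled to each requested depth and a
    Jukes–Cantor block of ``block_length`` sites is simulated on each
    scaled tree; blocks are concatenated, and ``true_labels[i]`` records
    the generating block of site i.
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    base = yule_tree(n_tips, birth, rng)
    trees = [scale_tree_depth(base, d) for d in depths]
    blocks = [simulate_alignment(t, block_length, rng) for t in trees]
    taxa = blocks[0].taxa
    mats = [b.matrix[[b.taxa.index(t) for t in taxa], :] for b in blocks]
    aln = Alignment(taxa, np.concatenate(mats, axis=1))
    labels = np.concatenate(
        [np.full(block_length, i, dtype=int) for i in range(len(depths))]
    )
    return SimulatedDataset(
        alignment=aln, true_labels=labels, trees=trees,
        params={
            "n_tips": n_tips, "birth": birth, "depths": tuple(depths),
            "block_length": block_length,
        },
    )


@dataclass
class PurityReport:
    """Per-subset majority-block purity with a threshold summary."""

    purities: list[float]
    threshold: float
    n_subsets: int
    n_high_purity: int

    @property
    def fraction_high_purity(self) -> float:
        return self.n_high_purity / self.n_subsets


def subset_purity(scheme_or_subsets, labels, threshold: float = 0.95) -> PurityReport:
    """Fraction of each subset's sites drawn from its majority generating
    block, plus the count of subsets at or above the purity threshold."""
    labels = np.asarray(labels)
    subsets = getattr(scheme_or_subsets, "subsets", scheme_or_subsets)
    purities = []
    for s in subsets:
        sites = np.asarray(getattr(s, "sites", s), dtype=int)
        if sites.min() < 0 or sites.max() >= labels.size:
            raise ValueError("subset site outside the labelled range")
        counts = np.bincount(labels[sites])
        purities.append(float(counts.max()) / sites.size)
    n_high = sum(1 for p in purities if p >= threshold)
    return PurityReport(
        purities=purities, threshold=threshold,
        n_subsets=len(purities), n_high_purity=n_high,
    )
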
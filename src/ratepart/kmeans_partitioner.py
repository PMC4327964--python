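"""Iterative k-means selection of phylogenetic partitioning schemes.

The algorithm starts from a single subset holding every alignment site,
with a best-fit substitution model chosen by AICc or BIC, and repeatedly
asks of each current subset: if its sites are split into two clusters by
k-means on per-site evolutionary rates (TIGER by default), and each new
subset gets its own best-fit model, does the information-theoretic score
of the whole scheme improve?  All subsets whose split improves the score
are divided simultaneously, and the loop repeats until no split is
accepted.  Branch lengths are linked: one shared relative-branch-length
tree, each subset scaling it by a single free rate multiplier.

Subsets that cannot be analysed reliably — too few sites, a single
distinct site pattern, or a degenerate optimiser — are flagged as
*problematic*: their site likelihoods are conservatively carried over
from the parent subset they were split from, they add no free
parameters, and after the loop terminates each is merged into the
non-problematic subset with the nearest rate centroid and the merged
subset is refitted.

Every accepted split strictly improves a bounded score and increases the
subset count, which cannot exceed the number of sites, so termination is
guaranteed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal
from typing import Sequence

import dendropy
import numpy as np

from .clustering import kmeans
from .model_selection import (
    AiccUndefinedError,
    ScoreResult,
    enumerate_candidate_models,
    information_score,
    score_result,
)
from .model_selection import select_best_model
from .msa_io import Alignment
from .phylo_likelihood import (
    FittedModel,
    ModelSpec,
    TreeArrays,
    bionj_tree,
    jc_distances,
    likelihood_site_rates,
    model_by_name,
    optimize_branch_lengths,
    prepare_subset,
)
from .tiger_rates import tiger_rates

__all__ = [
    "Subset",
    "PartitioningScheme",
    "PartitionerConfig",
    "SplitDecision",
    "score_scheme",
    "try_split",
    "iterative_kmeans",
    "merge_problematic",
    "count_partitioning_schemes",
]


@dataclass
class Subset:
    """A set of sites sharing one independently modelled substitution process."""

    sites: np.ndarray
    fitted: FittedModel | None = None
    score: ScoreResult | None = None
    centroid: float = math.nan
    problematic: bool = False
    carried_site_lnl: np.ndarray | None = None
    split_rejected: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        self.sites = np.asarray(self.sites, dtype=int)
        if self.sites.size == 0:
            raise ValueError("a subset must contain at least one site")
        if np.unique(self.sites).size != self.sites.size:
            raise ValueError("subset sites must be unique")
        self.sites = np.sort(self.sites)

    @property
    def n_sites(self) -> int:
        return int(self.sites.size)

    @property
    def lnL(self) -> float:
        if self.problematic:
            return float(self.carried_site_lnl.sum())
        return self.fitted.lnL

    @property
    def site_lnl(self) -> np.ndarray:
        return self.carried_site_lnl if self.problematic else self.fitted.site_lnl

    @property
    def model_k(self) -> int:
        # Problematic subsets are not independently modelled: no parameters.
        return 0 if self.problematic else self.fitted.n_free_params


@dataclass
class PartitioningScheme:
    """Disjoint subsets covering every alignment site exactly once."""

    subsets: list[Subset]
    score: ScoreResult | None = None
    history: list[dict] = field(default_factory=list)
    tree: dendropy.Tree | None = None

    @property
    def n_subsets(self) -> int:
        return len(self.subsets)

    def validate_coverage(self, n_sites: int) -> None:
        allsites = np.concatenate([s.sites for s in self.subsets])
        if allsites.size != n_sites or np.unique(allsites).size != allsites.size:
            raise ValueError("subsets must cover every site exactly once")
        if allsites.min() < 0 or allsites.max() >= n_sites:
            raise ValueError("subset site index out of range")

    def site_assignment(self, n_sites: int) -> np.ndarray:
        out = np.full(n_sites, -1, dtype=int)
        for idx, s in enumerate(self.subsets):
            out[s.sites] = idx
        return out


@dataclass
class PartitionerConfig:
    """Tunable knobs of the iterative partitioner."""

    metric: str = "bic"
    rate_method: str = "tiger"
    min_subset_size: int = 4
    kmeans_inits: int = 100
    candidates: Sequence[ModelSpec] | None = None
    bl_opt_sweeps: int = 3
    seed: int = 0


@dataclass
class SplitDecision:
    accept: bool
    children: tuple[Subset, Subset] | None
    old_value: float | None
    new_value: float | None
    reason: str = ""


def _scheme_totals(subsets: Sequence[Subset], n_taxa: int) -> tuple[float, int]:
    lnl = sum(s.lnL for s in subsets)
    n_nonprob = sum(1 for s in subsets if not s.problematic)
    k = (
        sum(s.model_k for s in subsets)
        + (2 * n_taxa - 3)
        + max(n_nonprob - 1, 0)
    )
    return float(lnl), int(k)


def score_scheme(
    scheme: PartitioningScheme,
    aln: Alignment,
    tree: dendropy.Tree | TreeArrays | None = None,
    metric: str = "bic",
) -> ScoreResult:
    """Scheme-level score: summed subset lnL, shared-tree parameter count,
    n = alignment length.  Validates that the subsets tile the alignment."""
    scheme.validate_coverage(aln.n_sites)
    lnl, k = _scheme_totals(scheme.subsets, aln.n_taxa)
    return score_result(lnl, k, aln.n_sites)


def _subset_rates(
    subset: Subset, aln: Alignment, ta: TreeArrays, rate_method: str
) -> np.ndarray:
    if rate_method == "tiger":
        return tiger_rates(aln, subset.sites).rates
    if rate_method == "likelihood":
        return likelihood_site_rates(aln, subset.sites, ta).rates
    raise ValueError(f"unknown rate method {rate_method!r}")


def _make_child(
    child_sites: np.ndarray,
    parent: Subset,
    rates: np.ndarray,
    rate_mask: np.ndarray,
    aln: Alignment,
    ta: TreeArrays,
    config: PartitionerConfig,
) -> Subset:
    centroid = float(rates[rate_mask].mean())
    data = prepare_subset(aln, child_sites)
    problematic = data.n_sites < config.min_subset_size or data.single_pattern
    fitted = None
    score = None
    if not problematic:
        fitted, score = select_best_model(
            data, ta, metric=config.metric, candidates=config.candidates,
            init_params=None if parent.fitted is None else parent.fitted.params,
        )
        problematic = fitted.flagged
    if problematic:
        # conservative carry-over: the child's site likelihoods are assumed
        # identical to their likelihoods inside the parent subset
        pos = np.searchsorted(parent.sites, child_sites)
        carried = parent.site_lnl[pos].copy()
        return Subset(
            sites=child_sites, centroid=centroid, problematic=True,
            carried_site_lnl=carried,
        )
    return Subset(sites=child_sites, fitted=fitted, score=score, centroid=centroid)


def try_split(
    subset: Subset,
    scheme: PartitioningScheme,
    aln: Alignment,
    tree: dendropy.Tree | TreeArrays,
    metric: str = "bic",
    rate_method: str = "tiger",
    rng: np.random.Generator | None = None,
    config: PartitionerConfig | None = None,
) -> SplitDecision:
    """Evaluate a single k=2 split of ``subset`` against the current scheme.

    Computes per-site rates for the focal subset, clusters them, fits a
    best model to each child, and accepts iff replacing the focal subset
    by the two children strictly improves the scheme-level metric.
    """
    config = config or PartitionerConfig(metric=metric, rate_method=rate_method)
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    ta = tree if isinstance(tree, TreeArrays) else TreeArrays(tree, aln.taxa)
    if subset.problematic:
        return SplitDecision(False, None, None, None, "problematic subset")
    if subset.n_sites < 2:
        return SplitDecision(False, None, None, None, "too few sites")
    rates = _subset_rates(subset, aln, ta, rate_method)
    if math.isnan(subset.centroid):
        subset.centroid = float(rates.mean())
    if np.unique(rates).size < 2:
        return SplitDecision(False, None, None, None, "single rate value")
    clust = kmeans(rates, k=2, n_init=config.kmeans_inits, rng=rng)
    if clust.degenerate:
        return SplitDecision(False, None, None, None, "degenerate clustering")
    mask0 = clust.labels == 0
    children = (
        _make_child(subset.sites[mask0], subset, rates, mask0, aln, ta, config),
        _make_child(subset.sites[~mask0], subset, rates, ~mask0, aln, ta, config),
    )
    if all(c.problematic for c in children):
        # carried likelihoods with fewer parameters would "improve" the
        # score without any new model; not a meaningful division
        return SplitDecision(False, None, None, None, "both children problematic")
    n = aln.n_sites
    others = [s for s in scheme.subsets if s is not subset]
    old_lnl, old_k = _scheme_totals(scheme.subsets, aln.n_taxa)
    new_lnl, new_k = _scheme_totals(others + list(children), aln.n_taxa)
    try:
        old_value = information_score(old_lnl, old_k, n, metric)
        new_value = information_score(new_lnl, new_k, n, metric)
    except AiccUndefinedError:
        return SplitDecision(False, children, None, None, "scheme AICc undefined")
    accept = new_value < old_value - 1e-9
    return SplitDecision(accept, children, old_value, new_value,
                         "score improved" if accept else "no improvement")


def build_starting_tree(
    aln: Alignment, bl_opt_sweeps: int = 3
) -> dendropy.Tree:
    """Step-1 pipeline: JC distances -> BioNJ -> GTR+I+G branch re-optimisation."""
    tree = bionj_tree(jc_distances(aln), aln.taxa)
    return optimize_branch_lengths(
        tree, aln, model_by_name("GTR+I+G"), max_sweeps=bl_opt_sweeps
    )


def iterative_kmeans(
    aln: Alignment,
    metric: str = "bic",
    rate_method: str = "tiger",
    rng: np.random.Generator | int | None = None,
    tree: dendropy.Tree | None = None,
    config: PartitionerConfig | None = None,
) -> PartitioningScheme:
    """Run the full iterative k-means partitioning algorithm.

    Returns the final scheme (after merging problematic subsets) with its
    score and a per-iteration history of scores and subset counts.
    """
    config = config or PartitionerConfig(metric=metric, rate_method=rate_method)
    config.metric = metric
    config.rate_method = rate_method
    if rng is None:
        rng = np.random.default_rng(config.seed)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if aln.n_taxa < 4:
        raise ValueError("iterative partitioning needs at least four taxa")
    if tree is None:
        tree = build_starting_tree(aln, bl_opt_sweeps=config.bl_opt_sweeps)
    ta = TreeArrays(tree, aln.taxa)

    data = prepare_subset(aln)
    fitted, sr = select_best_model(
        data, ta, metric=metric, candidates=config.candidates
    )
    if fitted.flagged:
        raise RuntimeError("the full alignment is not analyzable (degenerate fit)")
    root = Subset(sites=np.arange(aln.n_sites), fitted=fitted, score=sr)
    scheme = PartitioningScheme(subsets=[root], tree=tree)
    scheme.score = score_scheme(scheme, aln, ta, metric)
    scheme.history.append(_history_entry(scheme, 0, metric, "init"))

    iteration = 0
    while True:
        iteration += 1
        accepted: list[tuple[Subset, tuple[Subset, Subset]]] = []
        for s in scheme.subsets:
            if s.problematic or s.split_rejected or s.n_sites < 2:
                continue
            decision = try_split(
                s, scheme, aln, ta, metric=metric, rate_method=rate_method,
                rng=rng, config=config,
            )
            if decision.accept:
                accepted.append((s, decision.children))
            else:
                s.split_rejected = True
        if not accepted:
            break
        replaced = {id(s) for s, _ in accepted}
        new_subsets: list[Subset] = []
        for s in scheme.subsets:
            if id(s) in replaced:
                _, kids = next(pair for pair in accepted if pair[0] is s)
                new_subsets.extend(kids)
            else:
                new_subsets.append(s)
        scheme.subsets = new_subsets
        scheme.score = score_scheme(scheme, aln, ta, metric)
        scheme.history.append(_history_entry(scheme, iteration, metric, "split"))

    merge_problematic(scheme, aln, ta, metric=metric, config=config)
    scheme.score = score_scheme(scheme, aln, ta, metric)
    scheme.history.append(_history_entry(scheme, iteration, metric, "final"))
    return scheme


def _history_entry(
    scheme: PartitioningScheme, iteration: int, metric: str, phase: str
) -> dict:
    return {
        "iteration": iteration,
        "phase": phase,
        "n_subsets": scheme.n_subsets,
        "n_problematic": sum(1 for s in scheme.subsets if s.problematic),
        "lnL": scheme.score.lnL,
        "k": scheme.score.k,
        metric: scheme.score.value(metric),
    }


def merge_problematic(
    scheme: PartitioningScheme,
    aln: Alignment,
    tree: dendropy.Tree | TreeArrays,
    metric: str = "bic",
    config: PartitionerConfig | None = None,
) -> PartitioningScheme:
    """Merge every problematic subset into its nearest neighbour.

    The nearest neighbour is the non-problematic subset whose rate
    centroid is closest in Euclidean distance; the merged subset gets a
    freshly selected best model.  Repeats until no problematic subsets
    remain.  If everything is problematic the subsets collapse into one
    and a final fit is attempted; failure there is a hard error.
    """
    config = config or PartitionerConfig(metric=metric)
    ta = tree if isinstance(tree, TreeArrays) else TreeArrays(tree, aln.taxa)
    while True:
        problems = [s for s in scheme.subsets if s.problematic]
        if not problems:
            return scheme
        healthy = [s for s in scheme.subsets if not s.problematic]
        if not healthy:
            allsites = np.concatenate([s.sites for s in scheme.subsets])
            fitted, sr = select_best_model(
                prepare_subset(aln, np.sort(allsites)), ta,
                metric=metric, candidates=config.candidates,
            )
            if fitted.flagged:
                raise RuntimeError("alignment unanalyzable even as a single subset")
            scheme.subsets = [Subset(sites=np.sort(allsites), fitted=fitted, score=sr)]
            return scheme
        p = problems[0]
        nearest = min(healthy, key=lambda s: abs(s.centroid - p.centroid))
        merged_sites = np.sort(np.concatenate([p.sites, nearest.sites]))
        data = prepare_subset(aln, merged_sites)
        fitted, sr = select_best_model(
            data, ta, metric=metric, candidates=config.candidates,
            init_params=None if nearest.fitted is None else nearest.fitted.params,
        )
        centroid = (
            p.centroid * p.n_sites + nearest.centroid * nearest.n_sites
        ) / (p.n_sites + nearest.n_sites)
        merged = Subset(sites=merged_sites, centroid=centroid)
        if fitted.flagged:
            # still unanalyzable: carry its own fitted site likelihoods and
            # keep merging on the next pass
            merged.problematic = True
            merged.carried_site_lnl = fitted.site_lnl
        else:
            merged.fitted = fitted
            merged.score = sr
        scheme.subsets = [
            s for s in scheme.subsets if s is not p and s is not nearest
        ] + [merged]


def count_partitioning_schemes(n_sites: int) -> tuple[int, float]:
    """Number of possible partitioning schemes of ``n_sites`` sites.

    This is the Bell number B(n), computed exactly with the Bell-triangle
    recurrence; returns ``(B(n), log10 B(n))``.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    row = [1]
    for _ in range(n_sites - 1):
        new = [row[-1]]
        for v in row:
            new.append(new[-1] + v)
        row = new
    bell = row[-1]
    log10 = float(Decimal(bell).log10())
    return bell, log10
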
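"""Nucleotide likelihood engine.

Provides everything the partitioner needs from a phylogenetics toolkit:

* Jukes–Cantor pairwise distances and a BioNJ starting tree;
* Felsenstein-pruning log-likelihoods under the GTR submodel family,
  optionally with discrete-gamma rate heterogeneity (+G, 4 categories of
  equal prior weight with category-mean rates) and a proportion of
  invariant sites (+I);
* branch-length optimization on a fixed topology;
* per-subset model fits in which the *relative* branch lengths stay fixed
  and a single rate multiplier m stretches or shrinks them in tandem
  (the "linked branch lengths" convention);
* likelihood-based site rates (posterior-mean gamma-category rates);
* a basic NNI hill-climb used by the starting-tree bias pipeline.

Trees are dendropy objects; heavy computation runs on flattened arrays
(:class:`TreeArrays`).  Partial likelihoods are rescaled per internal node
so alignments with a hundred or more taxa do not underflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import dendropy
import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import gammainc
from scipy.stats import gamma as _gamma_dist

from .msa_io import IUPAC_CODES, Alignment

__all__ = [
    "ModelSpec",
    "FittedModel",
    "TreeArrays",
    "SubsetData",
    "BASE_MODEL_TABLE",
    "model_by_name",
    "discrete_gamma_rates",
    "prepare_subset",
    "jc_distances",
    "bionj_tree",
    "log_likelihood",
    "fit_model",
    "fit_model_data",
    "optimize_branch_lengths",
    "likelihood_site_rates",
    "nni_hill_climb",
]

N_GAMMA_CATEGORIES = 4
ALPHA_BOUNDS = (0.02, 100.0)
PINV_BOUNDS = (0.0, 0.99)
M_BOUNDS = (1e-6, 1e3)

# The six exchangeability slots, in the conventional order.
_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))  # AC AG AT CG CT GT

# 14 base models: 7 exchangeability tying patterns x {equal, estimated}
# frequencies.  Class ids per slot (AC, AG, AT, CG, CT, GT); slots sharing a
# class share a rate.  With the four heterogeneity variants (plain, +I, +G,
# +I+G) these span the standard 56-model GTR submodel census.
BASE_MODEL_TABLE: tuple[tuple[str, tuple[int, ...], bool], ...] = (
    ("JC", (0, 0, 0, 0, 0, 0), False),
    ("K80", (0, 1, 0, 0, 1, 0), False),
    ("TrNef", (0, 1, 0, 0, 2, 0), False),
    ("K81", (0, 1, 2, 2, 1, 0), False),
    ("TIMef", (0, 1, 2, 2, 3, 0), False),
    ("TVMef", (0, 1, 2, 3, 1, 4), False),
    ("SYM", (0, 1, 2, 3, 4, 5), False),
    ("F81", (0, 0, 0, 0, 0, 0), True),
    ("HKY", (0, 1, 0, 0, 1, 0), True),
    ("TrN", (0, 1, 0, 0, 2, 0), True),
    ("K81uf", (0, 1, 2, 2, 1, 0), True),
    ("TIM", (0, 1, 2, 2, 3, 0), True),
    ("TVM", (0, 1, 2, 3, 1, 4), True),
    ("GTR", (0, 1, 2, 3, 4, 5), True),
)


@dataclass(frozen=True)
class ModelSpec:
    """A GTR-family substitution model specification.

    ``exch_classes`` assigns each of the six exchangeability slots
    (AC, AG, AT, CG, CT, GT) to a tied rate class; slots with equal class
    ids share one rate, and the class containing GT is the reference
    fixed at 1.
    """

    base_name: str
    exch_classes: tuple[int, int, int, int, int, int]
    estimate_freqs: bool
    plus_I: bool = False
    plus_G: bool = False

    @property
    def name(self) -> str:
        suffix = ("+I" if self.plus_I else "") + ("+G" if self.plus_G else "")
        return self.base_name + suffix

    @property
    def n_exch_free(self) -> int:
        return len(set(self.exch_classes)) - 1

    @property
    def subset_free_params(self) -> int:
        """Model-level free parameters (excludes the subset rate multiplier)."""
        return (
            self.n_exch_free
            + (3 if self.estimate_freqs else 0)
            + (1 if self.plus_G else 0)
            + (1 if self.plus_I else 0)
        )


def model_by_name(name: str) -> ModelSpec:
    """Look up e.g. ``"GTR+I+G"`` or ``"JC"``."""
    plus_I = "+I" in name
    plus_G = "+G" in name
    base = name.replace("+I", "").replace("+G", "")
    for base_name, classes, est in BASE_MODEL_TABLE:
        if base_name == base:
            return ModelSpec(base_name, classes, est, plus_I=plus_I, plus_G=plus_G)
    raise KeyError(f"unknown model name: {name!r}")


@dataclass
class FittedModel:
    """A model fitted to one subset on a fixed relative-branch-length tree."""

    spec: ModelSpec
    lnL: float
    params: dict
    n_free_params: int
    site_lnl: np.ndarray  # per-site log-likelihood, aligned with the subset's site order
    flagged: bool = False


# ---------------------------------------------------------------------------
# Rate matrices and gamma categories


def _build_exch6(spec: ModelSpec, class_rates: dict[int, float]) -> np.ndarray:
    ref = spec.exch_classes[5]
    out = np.empty(6)
    for slot, cls in enumerate(spec.exch_classes):
        out[slot] = 1.0 if cls == ref else class_rates[cls]
    return out


def _eigen_system(exch6: np.ndarray, freqs: np.ndarray):
    """Eigendecomposition of the normalised reversible rate matrix.

    Returns ``(w, A, B)`` with ``P(t) = A @ diag(exp(w t)) @ B``; the matrix
    is scaled so one unit of branch length is one expected substitution.
    """
    freqs = np.asarray(freqs, dtype=float)
    Q = np.zeros((4, 4))
    for (i, j), r in zip(_PAIRS, exch6):
        Q[i, j] = r * freqs[j]
        Q[j, i] = r * freqs[i]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -float(freqs @ np.diag(Q))
    if mu <= 0:
        raise ValueError("degenerate rate matrix")
    Q /= mu
    sq = np.sqrt(freqs)
    S = (sq[:, None] * Q) / sq[None, :]
    w, U = np.linalg.eigh((S + S.T) / 2)
    A = U / sq[:, None]
    B = U.T * sq[None, :]
    return w, A, B


def discrete_gamma_rates(alpha: float, ncat: int = N_GAMMA_CATEGORIES) -> np.ndarray:
    """Category-mean rates of a mean-1 gamma discretised into equal bins."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    edges = _gamma_dist.ppf(np.linspace(0.0, 1.0, ncat + 1), a=alpha, scale=1.0 / alpha)
    upper = gammainc(alpha + 1.0, alpha * edges[1:])
    lower = gammainc(alpha + 1.0, alpha * edges[:-1])
    return ncat * (upper - lower)


# ---------------------------------------------------------------------------
# Tree flattening


class TreeArrays:
    """Array view of a dendropy tree for fast pruning.

    Tip node ids are 0..n_taxa-1 in the alignment's taxon order; internal
    nodes follow in postorder.  ``edge_lengths[i]`` is the length of the
    edge above node ``i`` (0 for the root).
    """

    def __init__(self, tree: dendropy.Tree, taxa: Sequence[str]):
        taxa = tuple(taxa)
        pos = {t: i for i, t in enumerate(taxa)}
        self.taxa = taxa
        n_taxa = len(taxa)
        ids: dict[int, int] = {}
        children: dict[int, list[int]] = {}
        lengths: dict[int, float] = {}
        node_refs: dict[int, dendropy.Node] = {}
        postorder: list[int] = []
        next_id = n_taxa
        for nd in tree.postorder_node_iter():
            if nd.is_leaf():
                if nd.taxon is None or nd.taxon.label not in pos:
                    label = None if nd.taxon is None else nd.taxon.label
                    raise ValueError(f"tree leaf {label!r} absent from alignment taxa")
                i = pos[nd.taxon.label]
            else:
                i = next_id
                next_id += 1
                children[i] = [ids[id(ch)] for ch in nd.child_nodes()]
                postorder.append(i)
            ids[id(nd)] = i
            node_refs[i] = nd
            lengths[i] = nd.edge.length if nd.edge.length is not None else 0.0
        if len([i for i in range(n_taxa) if i in node_refs]) != n_taxa:
            raise ValueError("tree does not cover all alignment taxa")
        self.n_taxa = n_taxa
        self.n_nodes = next_id
        self.root = postorder[-1]
        self.postorder = postorder
        self.children = children
        self.node_refs = node_refs
        self.edge_lengths = np.array([lengths[i] for i in range(next_id)])
        self.edge_lengths[self.root] = 0.0

    def apply_lengths(self) -> None:
        """Write the current edge lengths back onto the dendropy nodes."""
        for i, nd in self.node_refs.items():
            if i != self.root:
                nd.edge.length = float(self.edge_lengths[i])

    @property
    def n_edges(self) -> int:
        return self.n_nodes - 1


# ---------------------------------------------------------------------------
# Pattern data


@dataclass
class SubsetData:
    """Pattern-compressed view of one subset of alignment sites."""

    sites: np.ndarray
    weights: np.ndarray
    inverse: np.ndarray
    tip_partials: np.ndarray  # (n_taxa, n_patterns, 4)
    allow: np.ndarray  # (n_patterns, 4): 1 where every tip permits that constant state
    emp_freqs: np.ndarray

    @property
    def n_sites(self) -> int:
        return int(self.sites.size)

    @property
    def n_patterns(self) -> int:
        return int(self.weights.size)

    @property
    def single_pattern(self) -> bool:
        return self.n_patterns == 1


_CHAR_PARTIAL = {c: np.array([1.0 if k in allowed else 0.0 for k in range(4)])
                 for c, allowed in IUPAC_CODES.items()}


def prepare_subset(aln: Alignment, sites: Sequence[int] | None = None) -> SubsetData:
    if sites is None:
        sites = np.arange(aln.n_sites)
    sites = np.asarray(sites, dtype=int)
    if sites.size == 0:
        raise ValueError("empty subset")
    cols = aln.matrix[:, sites]
    uniq, inverse = np.unique(cols.T, axis=0, return_inverse=True)
    inverse = inverse.ravel()
    weights = np.bincount(inverse, minlength=uniq.shape[0]).astype(float)
    n_pat = uniq.shape[0]
    tipL = np.empty((aln.n_taxa, n_pat, 4))
    for t in range(aln.n_taxa):
        for p in range(n_pat):
            tipL[t, p] = _CHAR_PARTIAL[uniq[p, t]]
    allow = np.all(tipL > 0, axis=0).astype(float)
    codes = aln.codes()[:, sites]
    counts = np.array([(codes == b).sum() for b in range(4)], dtype=float)
    emp = counts / counts.sum() if counts.sum() > 0 else np.full(4, 0.25)
    emp = np.clip(emp, 1e-4, None)
    emp /= emp.sum()
    return SubsetData(
        sites=sites, weights=weights, inverse=inverse,
        tip_partials=tipL, allow=allow, emp_freqs=emp,
    )


# ---------------------------------------------------------------------------
# Core pruning likelihood


def _transition_matrices(w, A, B, t: np.ndarray) -> np.ndarray:
    """P over an array of scaled branch lengths ``t`` (..., shape S)."""
    expw = np.exp(np.multiply.outer(t, w))  # (..., 4)
    P = np.einsum("ik,...k,kj->...ij", A, expw, B)
    np.clip(P, 0.0, None, out=P)
    return P


def _root_partials(data: SubsetData, ta: TreeArrays, P: np.ndarray):
    """Conditional likelihoods at the root: (ncat, n_patterns, 4) + log scale."""
    npat = data.n_patterns
    ncat = P.shape[1]
    partial: list[np.ndarray | None] = [None] * ta.n_nodes
    log_scale = np.zeros(npat)
    tipL = data.tip_partials
    PT = P.transpose(0, 1, 3, 2)  # so contrib[c] = L[c] @ P[c].T via batched matmul
    for node in ta.postorder:
        prod: np.ndarray | None = None
        for ch in ta.children[node]:
            if ch < ta.n_taxa:
                contrib = np.matmul(tipL[ch][None, :, :], PT[ch])
            else:
                contrib = np.matmul(partial[ch], PT[ch])
                partial[ch] = None
            if prod is None:
                prod = contrib
            else:
                prod *= contrib
        mx = prod.max(axis=(0, 2))
        np.maximum(mx, 1e-300, out=mx)
        prod /= mx[None, :, None]
        log_scale += np.log(mx)
        partial[node] = prod
    return partial[ta.root], log_scale


def _pattern_likelihoods(data: SubsetData, ta: TreeArrays, spec: ModelSpec, params: dict):
    """Per-pattern log-likelihoods and per-gamma-category likelihoods.

    Returns ``(lnl, cat_like, cat_rates, log_scale)``; ``cat_like`` excludes
    the invariant-class mixture so it can drive posterior rate estimates.
    """
    freqs = np.asarray(params["freqs"], dtype=float)
    exch6 = np.asarray(params["exch"], dtype=float)
    m = float(params["m"])
    w, A, B = _eigen_system(exch6, freqs)
    if spec.plus_G:
        cat_rates = discrete_gamma_rates(float(params["alpha"]))
    else:
        cat_rates = np.array([1.0])
    t = np.multiply.outer(ta.edge_lengths * m, cat_rates)  # (nodes, ncat)
    P = _transition_matrices(w, A, B, t)
    root, log_scale = _root_partials(data, ta, P)
    cat_like = (root @ freqs).T  # (n_patterns, ncat)
    np.clip(cat_like, 0.0, None, out=cat_like)
    mean_like = cat_like.mean(axis=1)
    p_inv = float(params.get("p_inv", 0.0)) if spec.plus_I else 0.0
    with np.errstate(divide="ignore"):
        if p_inv > 0.0:
            inv_like = data.allow @ freqs
            la = np.log((1.0 - p_inv) * mean_like) + log_scale
            lb = np.log(p_inv * inv_like)
            lnl = np.logaddexp(la, lb)
        else:
            lnl = np.log(mean_like) + log_scale
    return lnl, cat_like, cat_rates, log_scale


def _total_lnl(data: SubsetData, ta: TreeArrays, spec: ModelSpec, params: dict) -> float:
    lnl, _, _, _ = _pattern_likelihoods(data, ta, spec, params)
    return float(lnl @ data.weights)


def log_likelihood(
    aln: Alignment,
    tree: dendropy.Tree | TreeArrays,
    fitted: FittedModel,
    sites: Sequence[int] | None = None,
) -> tuple[float, np.ndarray]:
    """Total and per-site log-likelihood of a fitted model on a subset."""
    data = prepare_subset(aln, sites)
    ta = tree if isinstance(tree, TreeArrays) else TreeArrays(tree, aln.taxa)
    lnl, _, _, _ = _pattern_likelihoods(data, ta, fitted.spec, fitted.params)
    per_site = lnl[data.inverse]
    return float(lnl @ data.weights), per_site


# ---------------------------------------------------------------------------
# Model fitting (fixed relative branch lengths, free rate multiplier)


class _ParamCodec:
    """Maps a model's free parameters to an unconstrained-ish bounded vector."""

    def __init__(self, spec: ModelSpec, emp_freqs: np.ndarray, fix_m: bool = False):
        self.spec = spec
        self.fix_m = fix_m
        self.entries: list[tuple[str, object]] = []
        x0: list[float] = []
        bounds: list[tuple[float, float]] = []
        if not fix_m:
            self.entries.append(("log_m", None))
            x0.append(0.0)
            bounds.append((math.log(M_BOUNDS[0]), math.log(M_BOUNDS[1])))
        ref = spec.exch_classes[5]
        self.free_classes = sorted(set(spec.exch_classes) - {ref})
        for cls in self.free_classes:
            self.entries.append(("log_exch", cls))
            x0.append(0.0)
            bounds.append((-7.0, 7.0))
        if spec.estimate_freqs:
            logits = np.log(emp_freqs / emp_freqs[3])
            for k in range(3):
                self.entries.append(("freq_logit", k))
                x0.append(float(np.clip(logits[k], -10, 10)))
                bounds.append((-12.0, 12.0))
        if spec.plus_G:
            self.entries.append(("log_alpha", None))
            x0.append(0.0)
            bounds.append((math.log(ALPHA_BOUNDS[0]), math.log(ALPHA_BOUNDS[1])))
        if spec.plus_I:
            self.entries.append(("p_inv", None))
            x0.append(0.1)
            bounds.append(PINV_BOUNDS)
        self.x0 = np.array(x0)
        self.bounds = bounds

    def encode(self, params: dict) -> np.ndarray:
        x = self.x0.copy()
        for i, (kind, key) in enumerate(self.entries):
            if kind == "log_m":
                x[i] = math.log(np.clip(params.get("m", 1.0), *M_BOUNDS))
            elif kind == "log_exch":
                classes = self.spec.exch_classes
                slot = classes.index(key)
                val = float(params.get("exch", np.ones(6))[slot])
                x[i] = math.log(np.clip(val, math.exp(-7), math.exp(7)))
            elif kind == "freq_logit":
                f = np.clip(np.asarray(params.get("freqs", np.full(4, 0.25))), 1e-6, None)
                x[i] = float(np.clip(math.log(f[key] / f[3]), -12, 12))
            elif kind == "log_alpha":
                x[i] = math.log(np.clip(params.get("alpha") or 1.0, *ALPHA_BOUNDS))
            elif kind == "p_inv":
                x[i] = float(np.clip(params.get("p_inv", 0.1), *PINV_BOUNDS))
        lo = np.array([b[0] for b in self.bounds])
        hi = np.array([b[1] for b in self.bounds])
        return np.clip(x, lo, hi)

    def decode(self, x: np.ndarray) -> dict:
        params = {"m": 1.0, "alpha": None, "p_inv": 0.0}
        class_rates: dict[int, float] = {}
        logits = np.zeros(4)
        for val, (kind, key) in zip(x, self.entries):
            if kind == "log_m":
                params["m"] = math.exp(val)
            elif kind == "log_exch":
                class_rates[key] = math.exp(val)
            elif kind == "freq_logit":
                logits[key] = val
            elif kind == "log_alpha":
                params["alpha"] = math.exp(val)
            elif kind == "p_inv":
                params["p_inv"] = float(val)
        params["exch"] = _build_exch6(self.spec, class_rates)
        if self.spec.estimate_freqs:
            e = np.exp(logits - logits.max())
            params["freqs"] = e / e.sum()
        else:
            params["freqs"] = np.full(4, 0.25)
        if self.spec.plus_G and params["alpha"] is None:
            params["alpha"] = 1.0
        return params


def fit_model_data(
    data: SubsetData,
    spec: ModelSpec,
    ta: TreeArrays,
    init_params: dict | None = None,
    fix_m: bool = False,
    maxfun: int = 400,
) -> FittedModel:
    """Fit one model to pattern data on a fixed-relative-branch-length tree."""
    codec = _ParamCodec(spec, data.emp_freqs, fix_m=fix_m)
    x0 = codec.encode(init_params) if init_params else codec.x0

    def objective(x: np.ndarray) -> float:
        val = _total_lnl(data, ta, spec, codec.decode(x))
        return -val if np.isfinite(val) else 1e12

    if codec.entries:
        res = minimize(
            objective, x0, method="L-BFGS-B", bounds=codec.bounds,
            options={"maxfun": maxfun, "ftol": 1e-8, "gtol": 1e-6},
        )
        best_x = res.x if res.fun <= objective(x0) else x0
    else:
        best_x = x0
    params = codec.decode(best_x)
    lnl, _, _, _ = _pattern_likelihoods(data, ta, spec, params)
    total = float(lnl @ data.weights)
    flagged = data.single_pattern
    m = params["m"]
    if not fix_m and (m <= M_BOUNDS[0] * 1.001 or m >= M_BOUNDS[1] * 0.999):
        flagged = True
    return FittedModel(
        spec=spec, lnL=total, params=params,
        n_free_params=spec.subset_free_params,
        site_lnl=lnl[data.inverse], flagged=flagged,
    )


def fit_model(
    aln: Alignment,
    sites: Sequence[int] | None,
    spec: ModelSpec,
    tree: dendropy.Tree | TreeArrays,
    init_params: dict | None = None,
) -> FittedModel:
    """Convenience wrapper around :func:`fit_model_data` for site lists."""
    data = prepare_subset(aln, sites)
    ta = tree if isinstance(tree, TreeArrays) else TreeArrays(tree, aln.taxa)
    return fit_model_data(data, spec, ta, init_params=init_params)


# ---------------------------------------------------------------------------
# Distances and BioNJ


def jc_distances(aln: Alignment, max_dist: float = 10.0) -> np.ndarray:
    """Jukes–Cantor distances d = -(3/4) ln(1 - 4p/3) over comparable sites."""
    codes = aln.codes()
    valid = codes >= 0
    T = aln.n_taxa
    D = np.zeros((T, T))
    for i in range(T):
        for j in range(i + 1, T):
            both = valid[i] & valid[j]
            n = int(both.sum())
            if n == 0:
                raise ValueError(
                    f"no comparable sites between {aln.taxa[i]!r} and {aln.taxa[j]!r}"
                )
            p = float((codes[i, both] != codes[j, both]).sum()) / n
            if p >= 0.75:
                d = max_dist
            else:
                d = min(-0.75 * math.log1p(-4.0 * p / 3.0), max_dist)
            D[i, j] = D[j, i] = d
    return D


def bionj_tree(D: np.ndarray, labels: Sequence[str]) -> dendropy.Tree:
    """BioNJ agglomeration: NJ topology/branch lengths with variance-weighted
    distance updates (lambda chosen to minimise the variance of the new
    distances).  Returns an unrooted tree with 2N-3 edges; negative branch
    length estimates are clamped to zero.
    """
    D = np.asarray(D, dtype=float)
    n0 = D.shape[0]
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if n0 != len(labels):
        raise ValueError("labels do not match matrix size")
    if n0 < 3:
        raise ValueError("need at least three taxa")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if (D < -1e-12).any():
        raise ValueError("distance matrix must be non-negative")

    tns = dendropy.TaxonNamespace()
    nodes: list[dendropy.Node] = []
    for lab in labels:
        nd = dendropy.Node(taxon=tns.new_taxon(label=str(lab)))
        nodes.append(nd)
    Dw = D.copy()
    Vw = D.copy()
    active = list(range(n0))

    def _submatrix(M):
        return M[np.ix_(active, active)]

    grow_D = Dw
    grow_V = Vw
    while len(active) > 3:
        n = len(active)
        Da = _submatrix(grow_D)
        Va = _submatrix(grow_V)
        R = Da.sum(axis=1)
        Qm = (n - 2) * Da - R[:, None] - R[None, :]
        np.fill_diagonal(Qm, np.inf)
        i_loc, j_loc = np.unravel_index(np.argmin(Qm), Qm.shape)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        d_ij = Da[i_loc, j_loc]
        b_i = 0.5 * d_ij + (R[i_loc] - R[j_loc]) / (2.0 * (n - 2))
        b_j = d_ij - b_i
        b_i, b_j = max(b_i, 0.0), max(b_j, 0.0)
        v_ij = Va[i_loc, j_loc]
        if v_ij > 1e-12:
            others = [k for k in range(n) if k not in (i_loc, j_loc)]
            lam = 0.5 + float(
                (Va[j_loc, others] - Va[i_loc, others]).sum()
            ) / (2.0 * (n - 2) * v_ij)
            lam = min(max(lam, 0.0), 1.0)
        else:
            lam = 0.5
        parent = dendropy.Node()
        gi, gj = active[i_loc], active[j_loc]
        nodes[gi].edge.length = b_i
        nodes[gj].edge.length = b_j
        parent.add_child(nodes[gi])
        parent.add_child(nodes[gj])
        new_D = lam * (grow_D[gi, active] - b_i) + (1 - lam) * (grow_D[gj, active] - b_j)
        new_V = lam * grow_V[gi, active] + (1 - lam) * grow_V[gj, active] - lam * (1 - lam) * v_ij
        new_D = np.maximum(new_D, 0.0)
        new_V = np.maximum(new_V, 0.0)
        size = grow_D.shape[0] + 1
        D2 = np.zeros((size, size))
        V2 = np.zeros((size, size))
        D2[:-1, :-1] = grow_D
        V2[:-1, :-1] = grow_V
        D2[-1, active] = new_D
        D2[active, -1] = new_D
        V2[-1, active] = new_V
        V2[active, -1] = new_V
        grow_D, grow_V = D2, V2
        nodes.append(parent)
        new_idx = size - 1
        active = [k for k in active if k not in (gi, gj)] + [new_idx]

    a, b, c = active
    d_ab, d_ac, d_bc = grow_D[a, b], grow_D[a, c], grow_D[b, c]
    center = dendropy.Node()
    for node_idx, length in (
        (a, (d_ab + d_ac - d_bc) / 2.0),
        (b, (d_ab + d_bc - d_ac) / 2.0),
        (c, (d_ac + d_bc - d_ab) / 2.0),
    ):
        nodes[node_idx].edge.length = max(float(length), 0.0)
        center.add_child(nodes[node_idx])
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = center
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Branch-length optimization

# Per-branch optimization uses the standard inner/outer-partial factorisation:
# with D_v the conditional likelihood of the data below node v and F_v the
# likelihood of everything outside v's subtree (stationary frequencies placed
# at v's parent, valid under reversibility), the site likelihood is
# F_v . P(t) . D_v — a function of the one branch length t being optimized.


def _inner_partials(data: SubsetData, ta: TreeArrays, PT: np.ndarray):
    """D_v (kept for every internal node) with per-pattern log scales."""
    npat = data.n_patterns
    D: list[np.ndarray | None] = [None] * ta.n_nodes
    sD: list[np.ndarray | None] = [None] * ta.n_nodes
    tipL = data.tip_partials
    for node in ta.postorder:
        prod: np.ndarray | None = None
        scale = np.zeros(npat)
        for ch in ta.children[node]:
            if ch < ta.n_taxa:
                contrib = np.matmul(tipL[ch][None, :, :], PT[ch])
            else:
                contrib = np.matmul(D[ch], PT[ch])
                scale += sD[ch]
            prod = contrib if prod is None else prod * contrib
        mx = prod.max(axis=(0, 2))
        np.maximum(mx, 1e-300, out=mx)
        prod /= mx[None, :, None]
        D[node] = prod
        sD[node] = scale + np.log(mx)
    return D, sD


def _outer_partials(data: SubsetData, ta: TreeArrays, P: np.ndarray,
                    D, sD, freqs: np.ndarray):
    """F_v and its log scales for every non-root node."""
    npat = data.n_patterns
    ncat = P.shape[1]
    PT = P.transpose(0, 1, 3, 2)
    tipL = data.tip_partials
    M: dict[int, np.ndarray] = {}
    msc: dict[int, np.ndarray | float] = {}
    for node in range(ta.n_nodes):
        if node == ta.root:
            continue
        if node < ta.n_taxa:
            M[node] = np.matmul(tipL[node][None, :, :], PT[node])
            msc[node] = 0.0
        else:
            M[node] = np.matmul(D[node], PT[node])
            msc[node] = sD[node]
    F: list[np.ndarray | None] = [None] * ta.n_nodes
    sF: list[np.ndarray | None] = [None] * ta.n_nodes
    for v in reversed(ta.postorder):  # root first, parents before children
        kids = ta.children[v]
        if v == ta.root:
            up = np.broadcast_to(freqs, (ncat, npat, 4))
            up_scale = np.zeros(npat)
        else:
            up = np.matmul(F[v], P[v])
            up_scale = sF[v]
        for c in kids:
            prod = up.copy()
            scale = up_scale.copy()
            for s in kids:
                if s is c:
                    continue
                prod = prod * M[s]
                scale = scale + msc[s]
            mx = prod.max(axis=(0, 2))
            np.maximum(mx, 1e-300, out=mx)
            prod /= mx[None, :, None]
            F[c] = prod
            sF[c] = scale + np.log(mx)
    return F, sF


def optimize_branch_lengths(
    tree: dendropy.Tree,
    aln: Alignment,
    spec: ModelSpec | None = None,
    tol: float = 1e-3,
    max_sweeps: int = 5,
    max_branch_length: float = 20.0,
) -> dendropy.Tree:
    """Optimize branch lengths on a fixed topology.

    Alternates model-parameter fits (rate multiplier fixed at 1 so lengths
    are identifiable) with sweeps of bounded one-dimensional Brent searches
    over each branch — each against fresh inner/outer partials, so a branch
    update is exact given the current remaining lengths — until the total
    log-likelihood improves by less than ``tol`` over a sweep.  The returned
    tree's likelihood is never worse than the input tree's.
    """
    spec = spec or model_by_name("GTR+I+G")
    tree = tree.clone(depth=1)
    data = prepare_subset(aln)
    ta = TreeArrays(tree, aln.taxa)
    fitted = fit_model_data(data, spec, ta, fix_m=True)
    params = fitted.params
    current = fitted.lnL
    weights = data.weights
    for _ in range(max_sweeps):
        before = current
        freqs = np.asarray(params["freqs"], dtype=float)
        w, A, B = _eigen_system(np.asarray(params["exch"], dtype=float), freqs)
        cat_rates = (
            discrete_gamma_rates(float(params["alpha"])) if spec.plus_G
            else np.array([1.0])
        )
        p_inv = float(params.get("p_inv", 0.0)) if spec.plus_I else 0.0
        log_inv = None
        if p_inv > 0:
            with np.errstate(divide="ignore"):
                log_inv = np.log(p_inv * (data.allow @ freqs))
        for v in range(ta.n_nodes):
            if v == ta.root:
                continue
            t_all = np.multiply.outer(ta.edge_lengths, cat_rates)
            P = _transition_matrices(w, A, B, t_all)
            D, sD = _inner_partials(data, ta, P.transpose(0, 1, 3, 2))
            F, sF = _outer_partials(data, ta, P, D, sD, freqs)
            if v < ta.n_taxa:
                base = data.tip_partials[v][None, :, :]
                base_scale = 0.0
            else:
                base = D[v]
                base_scale = sD[v]
            Fv, sFv = F[v], sF[v]

            def edge_lnl(t: float) -> float:
                expw = np.exp(np.multiply.outer(t * cat_rates, w))
                Pt = np.einsum("ik,ck,kj->cij", A, expw, B)
                np.clip(Pt, 0.0, None, out=Pt)
                tmp = np.matmul(Fv, Pt)
                site = (tmp * base).sum(axis=2).mean(axis=0)
                with np.errstate(divide="ignore"):
                    lnl = np.log((1.0 - p_inv) * site) + sFv + base_scale
                    if log_inv is not None:
                        lnl = np.logaddexp(lnl, log_inv)
                total = float(lnl @ weights)
                return total if np.isfinite(total) else -1e12

            res = minimize_scalar(
                lambda t: -edge_lnl(t),
                bounds=(1e-9, max_branch_length), method="bounded",
                options={"xatol": 1e-6, "maxiter": 40},
            )
            if -res.fun > edge_lnl(float(ta.edge_lengths[v])):
                ta.edge_lengths[v] = float(res.x)
        fitted = fit_model_data(data, spec, ta, init_params=params, fix_m=True)
        if fitted.lnL > current:
            current = fitted.lnL
            params = fitted.params
        if current - before < tol:
            break
    ta.apply_lengths()
    return tree


# ---------------------------------------------------------------------------
# Likelihood-based site rates


def likelihood_site_rates(
    aln: Alignment,
    sites: Sequence[int] | None,
    tree: dendropy.Tree | TreeArrays,
    fitted: FittedModel | None = None,
):
    """Posterior-mean gamma-category rates per site under a GTR+G fit.

    The rate of a site is sum_c r_c P(c | site) with equal category priors;
    a large alpha collapses every rate to 1.
    """
    from .tiger_rates import SiteRates  # local import avoids a cycle

    data = prepare_subset(aln, sites)
    ta = tree if isinstance(tree, TreeArrays) else TreeArrays(tree, aln.taxa)
    if fitted is None or not fitted.spec.plus_G:
        fitted = fit_model_data(data, model_by_name("GTR+G"), ta)
    _, cat_like, cat_rates, _ = _pattern_likelihoods(data, ta, fitted.spec, fitted.params)
    denom = cat_like.sum(axis=1)
    denom[denom <= 0] = 1.0
    post = cat_like / denom[:, None]
    pattern_rates = post @ cat_rates
    return SiteRates(
        rates=pattern_rates[data.inverse], method="likelihood", sites=data.sites,
        flagged=None,
    )


# ---------------------------------------------------------------------------
# NNI hill-climb (simplified topology search for the bias-test pipeline)


def nni_hill_climb(
    tree: dendropy.Tree,
    score_fn: Callable[[dendropy.Tree], float],
    max_rounds: int = 20,
) -> tuple[dendropy.Tree, float]:
    """First-improvement nearest-neighbour-interchange search.

    ``score_fn`` maps a tree to a score (higher is better, e.g. a partitioned
    log-likelihood).  This is a deliberately simple local search over NNI
    neighbourhoods on a fixed branch-length skeleton — a lightweight
    topology refiner, not a full ML tree search.
    """
    tree = tree.clone(depth=1)
    best = score_fn(tree)
    for _ in range(max_rounds):
        improved = False
        internal = [
            nd for nd in tree.preorder_node_iter()
            if nd.parent_node is not None and not nd.is_leaf()
        ]
        for v in internal:
            u = v.parent_node
            siblings = [s for s in u.child_nodes() if s is not v]
            if not siblings or len(v.child_nodes()) < 2:
                continue
            s = siblings[0]
            for c in list(v.child_nodes()):
                # swap s (child of u) with c (child of v)
                u.remove_child(s)
                v.remove_child(c)
                u.add_child(c)
                v.add_child(s)
                cand = score_fn(tree)
                if cand > best + 1e-9:
                    best = cand
                    improved = True
                    break
                u.remove_child(c)
                v.remove_child(s)
                u.add_child(s)
                v.add_child(c)
            if improved:
                break
        if not improved:
            break
    return tree, best
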
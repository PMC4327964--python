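"""Candidate model enumeration and AICc/BIC scoring.

The candidate set is the classical census of 56 GTR submodels: 14 base
models (7 exchangeability tying patterns, each with equal or estimated
base frequencies) crossed with the four rate-heterogeneity variants
{plain, +I, +G, +I+G}.

Two parameter-counting contexts exist:

* subset level — the model's own free parameters (exchangeabilities,
  frequencies, alpha, p_inv).  The per-subset rate multiplier is shared in
  form by every candidate, so it is excluded here and enters only at
  scheme level.  n is the subset length.
* scheme level — the sum of subset-level counts plus the 2N-3 shared
  branch lengths and s-1 free rate multipliers (one subset's multiplier
  is the reference).  n is the full alignment length, so schemes are
  compared on a common sample size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np

from .msa_io import Alignment
from .phylo_likelihood import (
    BASE_MODEL_TABLE,
    FittedModel,
    ModelSpec,
    SubsetData,
    TreeArrays,
    fit_model_data,
    prepare_subset,
)

__all__ = [
    "ScoreResult",
    "enumerate_candidate_models",
    "count_free_parameters",
    "scheme_free_parameters",
    "information_score",
    "select_best_model",
    "AiccUndefinedError",
]

_VARIANTS = ((False, False), (True, False), (False, True), (True, True))  # (+I, +G)


class AiccUndefinedError(ValueError):
    """AICc is undefined when n <= k + 1 (over-parameterised subset)."""


@dataclass(frozen=True)
class ScoreResult:
    """Log-likelihood with its information-theoretic scores."""

    lnL: float
    k: int
    n: int
    aicc: float | None
    bic: float

    def value(self, metric: str) -> float:
        if metric == "aicc":
            if self.aicc is None:
                raise AiccUndefinedError(f"AICc undefined for n={self.n}, k={self.k}")
            return self.aicc
        if metric == "bic":
            return self.bic
        raise ValueError(f"unknown metric {metric!r}")


def enumerate_candidate_models() -> list[ModelSpec]:
    """The 56 candidate specs in a stable simple-first order."""
    specs = []
    for base_name, classes, est in BASE_MODEL_TABLE:
        for plus_I, plus_G in _VARIANTS:
            specs.append(ModelSpec(base_name, classes, est, plus_I=plus_I, plus_G=plus_G))
    return specs


def count_free_parameters(
    spec: ModelSpec,
    scheme_subsets: Sequence[ModelSpec] | None = None,
    n_taxa: int | None = None,
) -> int:
    """Free parameters of one model (subset level) or of a whole scheme.

    With only ``spec``, returns the subset-level count.  With
    ``scheme_subsets`` and ``n_taxa``, returns the scheme-level total for
    those subset models (``spec`` is ignored in that case).
    """
    if scheme_subsets is None:
        return spec.subset_free_params
    if n_taxa is None:
        raise ValueError("scheme-level counting needs n_taxa")
    return scheme_free_parameters(scheme_subsets, n_taxa)


def scheme_free_parameters(subset_specs: Sequence[ModelSpec], n_taxa: int) -> int:
    """Sum of subset counts + (2N-3) branch lengths + (s-1) multipliers."""
    s = len(subset_specs)
    return sum(sp.subset_free_params for sp in subset_specs) + (2 * n_taxa - 3) + (s - 1)


def information_score(lnL: float, k: int, n: int, metric: str = "bic") -> float:
    """AICc = -2lnL + 2k + 2k(k+1)/(n-k-1); BIC = -2lnL + k ln n."""
    if metric == "aicc":
        if n <= k + 1:
            raise AiccUndefinedError(f"AICc undefined for n={n}, k={k}")
        return -2.0 * lnL + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)
    if metric == "bic":
        return -2.0 * lnL + k * math.log(n)
    raise ValueError(f"unknown metric {metric!r}")


def score_result(lnL: float, k: int, n: int) -> ScoreResult:
    try:
        aicc = information_score(lnL, k, n, "aicc")
    except AiccUndefinedError:
        aicc = None
    return ScoreResult(lnL=lnL, k=k, n=n, aicc=aicc, bic=information_score(lnL, k, n, "bic"))


def select_best_model(
    aln_or_data: Alignment | SubsetData,
    tree: dendropy.Tree | TreeArrays,
    metric: str = "bic",
    sites: Sequence[int] | None = None,
    candidates: Sequence[ModelSpec] | None = None,
    taxa: Sequence[str] | None = None,
    init_params: dict | None = None,
) -> tuple[FittedModel, ScoreResult]:
    """Fit every candidate to the subset and return the metric minimiser.

    Ranking uses subset-level k and n = subset length.  Candidates whose
    AICc is undefined at this n are skipped; ties break in favour of the
    earlier (simpler) candidate.  The degenerate-subset flag of the winning
    fit is propagated.
    """
    if isinstance(aln_or_data, SubsetData):
        data = aln_or_data
        if not isinstance(tree, TreeArrays):
            if taxa is None:
                raise ValueError("taxa required when passing SubsetData with a raw tree")
            tree = TreeArrays(tree, taxa)
    else:
        data = prepare_subset(aln_or_data, sites)
        if not isinstance(tree, TreeArrays):
            tree = TreeArrays(tree, aln_or_data.taxa)
    candidates = list(candidates) if candidates is not None else enumerate_candidate_models()
    best: tuple[FittedModel, ScoreResult] | None = None
    n = data.n_sites
    for spec in candidates:
        if metric == "aicc" and n <= spec.subset_free_params + 1:
            continue
        fitted = fit_model_data(data, spec, tree, init_params=init_params)
        sr = score_result(fitted.lnL, spec.subset_free_params, n)
        if best is None or sr.value(metric) < best[1].value(metric) - 1e-12:
            best = (fitted, sr)
    if best is None:
        raise AiccUndefinedError(
            f"no candidate model has a defined {metric} at n={n} sites"
        )
    return best
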
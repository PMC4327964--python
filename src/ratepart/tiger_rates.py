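"""TIGER site rates (Tree Independent Generation of Evolutionary Rates).

Every alignment column induces a *set partition* P(i) of the sequence
indices: one block per nucleotide observed at the site.  Columns are then
compared with the partition agreement score

    pa(i, j) = ( sum over blocks x of P(j) of a(x, P(i)) ) / |P(j)|

where a(x, P(i)) is 1 when block x is nested inside some block of P(i)
and 0 otherwise.  The rate of site i is the mean of pa(i, j) over every
other site j in the analysed pool:

    r_i = sum_{j != i} pa(i, j) / (n - 1)

Rates lie in [0, 1]; a site identical in partition to the whole pool —
in particular any invariant site — scores exactly 1.0, while sites that
disagree with most of the pool approach 0.  Only the partition matters:
"AACGGA" and "TTGAAT" induce the same P(i) and hence the same rate.

Rows carrying gaps or ambiguity codes at a site are assigned to no block.
A column with no unambiguous base at all (all-gap) is treated as maximally
uninformative: it contributes pa = 1 to every site and itself receives
rate 1.0, and is flagged so the partitioner can treat it as problematic.

The implementation compares distinct weighted site patterns only; the
self-comparison of a site with itself is removed by subtracting one from
its own pattern's weight, which reproduces the sum over j != i exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .msa_io import Alignment, _BASE_INDEX

__all__ = [
    "SetPartition",
    "SiteRates",
    "build_set_partition",
    "partition_agreement",
    "tiger_rates",
    "DegenerateColumnError",
]


class DegenerateColumnError(ValueError):
    """Raised when an operation requires a non-degenerate set partition."""


@dataclass(frozen=True)
class SetPartition:
    """The set partition P(i) of sequence indices induced by one column.

    ``blocks`` holds up to four disjoint frozensets of 0-based row indices,
    one per unambiguous nucleotide observed at the site.
    """

    blocks: tuple[frozenset[int], ...]

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for b in self.blocks:
            if seen & b:
                raise ValueError("set-partition blocks must be disjoint")
            seen |= b

    @property
    def cardinality(self) -> int:
        """|P(i)|: the number of non-empty blocks."""
        return len(self.blocks)

    @property
    def degenerate(self) -> bool:
        """True when the column carries no unambiguous nucleotide."""
        return len(self.blocks) == 0


@dataclass
class SiteRates:
    """Per-site rate vector for one analysed pool of sites."""

    rates: np.ndarray
    method: str
    sites: np.ndarray
    flagged: np.ndarray | None = None  # True where the column was all-gap


def build_set_partition(column: Sequence[str]) -> SetPartition:
    """Group row indices by the unambiguous nucleotide they carry.

    Gap/ambiguity rows belong to no block; a column of only such rows
    yields the degenerate zero-block partition.
    """
    groups: dict[int, list[int]] = {}
    for row, ch in enumerate(column):
        idx = _BASE_INDEX.get(str(ch).upper())
        if idx is not None:
            groups.setdefault(idx, []).append(row)
    blocks = tuple(frozenset(groups[k]) for k in sorted(groups))
    return SetPartition(blocks)


def partition_agreement(p_i: SetPartition, p_j: SetPartition) -> float:
    """pa(i, j): fraction of blocks of P(j) nested inside blocks of P(i).

    Asymmetric in its arguments.  Raises for a degenerate P(j); callers
    that tolerate all-gap columns apply the rate-1 convention themselves.
    """
    if p_j.degenerate:
        raise DegenerateColumnError("pa undefined for a zero-block P(j)")
    hits = 0
    for x in p_j.blocks:
        if any(x <= a for a in p_i.blocks):
            hits += 1
    return hits / p_j.cardinality


def _pattern_agreement_matrix(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """pa between all pairs of site patterns.

    ``codes``: (n_taxa, n_patterns) int8, values 0..3 or -1 for no block.
    Returns (pa, degenerate_mask) with pa[i, j] = pa(pattern i, pattern j).
    Degenerate (all -1) patterns get pa = 1 as both donor and recipient.
    """
    n_taxa, n_pat = codes.shape
    pa = np.zeros((n_pat, n_pat))
    degenerate = np.all(codes < 0, axis=0)
    for j in range(n_pat):
        col = codes[:, j]
        n_blocks = 0
        contained = np.zeros(n_pat)
        for b in range(4):
            rows = col == b
            if not rows.any():
                continue
            n_blocks += 1
            sub = codes[rows, :]  # (block size, n_patterns)
            lo = sub.min(axis=0)
            contained += (lo == sub.max(axis=0)) & (lo >= 0)
        if n_blocks:
            pa[:, j] = contained / n_blocks
    pa[:, degenerate] = 1.0
    pa[degenerate, :] = 1.0
    return pa, degenerate


def tiger_rates(aln: Alignment, sites: Sequence[int] | None = None) -> SiteRates:
    """TIGER rates for the selected site pool (default: whole alignment).

    Rates depend on the pool: the same column generally gets a different
    rate inside a sub-alignment than in the full alignment, so rates are
    recomputed per subset by the partitioner.
    """
    if sites is None:
        sites = np.arange(aln.n_sites)
    sites = np.asarray(sites, dtype=int)
    n = sites.size
    if n < 2:
        raise ValueError("TIGER rates need at least two sites (n - 1 > 0)")
    codes = aln.codes()[:, sites]  # (T, n)
    pat, inverse = np.unique(codes.T, axis=0, return_inverse=True)
    inverse = inverse.ravel()
    weights = np.bincount(inverse, minlength=pat.shape[0]).astype(float)
    pa, degenerate = _pattern_agreement_matrix(pat.T)
    # r for pattern p: (sum_j w_j pa[p, j] - pa[p, p]) / (n - 1); the
    # subtraction removes the single self-pair of each site.
    totals = pa @ weights - np.diag(pa)
    pattern_rates = totals / (n - 1)
    rates = pattern_rates[inverse]
    flagged = degenerate[inverse]
    return SiteRates(rates=rates, method="tiger", sites=sites, flagged=flagged)
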
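"""Exact 2x2 inference, the fold-change (F) score, and p-value decile bins.

The two-sided Fisher exact p-value is computed with exact integer
arithmetic: hypergeometric point masses share one denominator, so summing
the integer numerators that do not exceed the observed one gives the
point-probability two-sided p with no floating-point tie ambiguity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from math import comb

import numpy as np

from .types import ContingencyCounts

__all__ = [
    "FisherResult",
    "fisher_exact_2x2",
    "fscore",
    "BinPartition",
    "make_bins",
    "PAPER_DECILE_EDGES",
]

#: Empirical decile edges of the published schizophrenia analysis, for
#: fixed-edge replication-style runs (descending p order as printed).
PAPER_DECILE_EDGES = (1.0, 0.886, 0.781, 0.671, 0.559, 0.443, 0.336, 0.233, 0.140, 0.054, 0.0)


@dataclass(frozen=True)
class FisherResult:
    odds_ratio: float
    p_value: float
    zero_margin: bool = False


def fisher_exact_2x2(table) -> FisherResult:
    """Two-sided Fisher exact test for a 2x2 table of nonnegative counts.

    The p-value is the sum of hypergeometric probabilities, over all tables
    with the observed margins, whose point probability does not exceed the
    observed table's (the point-probability two-sided rule). A table with
    any zero margin has p = 1 by convention and is flagged. The odds ratio
    is the sample odds ratio a*d / (b*c).
    """
    (a, b), (c, d) = table
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("table entries must be nonnegative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    n = r1 + r2

    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)

    if min(r1, r2, c1, c2) == 0:
        return FisherResult(odds_ratio=odds, p_value=1.0, zero_margin=True)

    # Integer numerators N_k = C(r1, k) * C(r2, c1 - k) over the support,
    # via an exact multiplicative recurrence; common denominator C(n, c1).
    kmin = max(0, c1 - r2)
    kmax = min(r1, c1)
    nk = comb(r1, kmin) * comb(r2, c1 - kmin)
    n_obs = None
    numerators = []
    k = kmin
    while True:
        numerators.append(nk)
        if k == a:
            n_obs = nk
        if k == kmax:
            break
        nk = nk * (r1 - k) * (c1 - k) // ((k + 1) * (r2 - c1 + k + 1))
        k += 1

    selected = sum(v for v in numerators if v <= n_obs)
    p = selected / comb(n, c1)
    return FisherResult(odds_ratio=odds, p_value=min(1.0, p))


def fscore(counts: ContingencyCounts, convention: str = "printed") -> float:
    """Fold-change enrichment score for one bin and one site class.

    With a = all analyzed SNPs, b = those in sites, c = SNPs in the bin and
    d = in-bin SNPs in sites, the ``printed`` convention returns
    (b*c)/(a*d) and ``obs_exp`` returns its reciprocal (a*d)/(b*c), the
    in-bin site proportion d/c over the genome-wide proportion b/a. NaN
    when the respective denominator is zero (no SNPs at all, an empty bin,
    or no site SNPs where the formula divides by them).
    """
    a, b, c, d = counts.a, counts.b, counts.c, counts.d
    if convention == "printed":
        return (b * c) / (a * d) if a * d > 0 else math.nan
    if convention == "obs_exp":
        return (a * d) / (b * c) if b * c > 0 else math.nan
    raise ValueError(f"unknown F-score convention: {convention!r}")


@dataclass(frozen=True)
class BinPartition:
    """Ten (by default) p-value intervals covering [0, 1].

    ``edges`` is ascending with edges[0] = 0 and edges[-1] = 1. Bin indices
    run from the highest-p interval (index 0) down to the lowest-p interval
    (index n_bins - 1), matching the convention of listing deciles from
    p ~ 1 downwards. Each interval is half-open (lower, upper], except the
    lowest-p interval which is closed at 0; a p equal to an interior edge
    therefore falls in the interval having that edge as its upper bound.
    """

    edges: tuple

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    def upper(self, bin_index: int) -> float:
        return self.edges[self.n_bins - bin_index]

    def lower(self, bin_index: int) -> float:
        return self.edges[self.n_bins - bin_index - 1]

    def assign(self, p_values) -> np.ndarray:
        """Vector of bin indices, one per p-value."""
        p = np.asarray(p_values, dtype=float)
        if p.size and (not np.all(np.isfinite(p)) or p.min() < 0 or p.max() > 1):
            raise ValueError("p-values must be finite and within [0, 1]")
        edges = np.asarray(self.edges)
        low_idx = np.clip(np.searchsorted(edges, p, side="left") - 1, 0, self.n_bins - 1)
        return (self.n_bins - 1 - low_idx).astype(np.int64)


def make_bins(p_values, n_bins: int = 10, mode: str = "empirical", edges=None) -> BinPartition:
    """Build the p-value bin partition.

    ``empirical`` places edges at the sample quantiles of the analyzed
    SNPs' p-values (the default, since published decile edges are
    data-derived); ``fixed`` applies user-supplied edges verbatim, e.g.
    :data:`PAPER_DECILE_EDGES`. Fixed edges must include 0 and 1.
    """
    if mode == "empirical":
        p = np.asarray(p_values, dtype=float)
        if not np.all(np.isfinite(p)):
            raise ValueError("p-values must be finite")
        if p.size < n_bins:
            raise ValueError(f"need at least {n_bins} p-values for {n_bins} bins")
        qs = np.quantile(p, np.arange(1, n_bins) / n_bins)
        return BinPartition(edges=(0.0, *(float(q) for q in qs), 1.0))
    if mode == "fixed":
        if edges is None:
            raise ValueError("fixed mode requires edges")
        e = sorted(float(x) for x in edges)
        if e[0] != 0.0 or e[-1] != 1.0 or len(set(e)) != len(e):
            raise ValueError("fixed edges must be distinct and include 0 and 1")
        return BinPartition(edges=tuple(e))
    raise ValueError(f"unknown bin mode: {mode!r}")
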
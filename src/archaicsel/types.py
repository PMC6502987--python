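"""Structured domain types shared across the pipeline.

Tabular data (GWAS summary statistics, site catalogs, MAF tables, annotated
SNP sets) travels as pandas DataFrames with the column schemas documented in
:mod:`archaicsel.io`; the small fixed-shape values below are dataclasses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

NUCLEOTIDES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

LINEAGE_MD = "MD"
LINEAGE_AD = "AD"
LINEAGES = (LINEAGE_MD, LINEAGE_AD)

POLARITY_DERIVED_RISK = "derived_risk"
POLARITY_DERIVED_PROTECTIVE = "derived_protective"
POLARITY_UNRESOLVED = "unresolved"


@dataclass(frozen=True)
class ContingencyCounts:
    """The a/b/c/d counts behind one bin's fold-change score.

    a: all analyzed SNPs genome-wide; b: analyzed SNPs within MD (or AD)
    sites; c: SNPs in the queried p-value bin genome-wide; d: SNPs in the
    queried bin within MD (or AD) sites.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be nonnegative")
        if self.b > self.a or self.d > self.c or self.d > self.b:
            raise ValueError(
                f"inconsistent counts a={self.a} b={self.b} c={self.c} d={self.d}"
            )


@dataclass
class BinResult:
    """Per-bin enrichment and polarity-ratio results for both lineages.

    Undefined statistics (zero denominators, empty bins) are NaN and are
    written out as the "NA" sentinel.
    """

    bin_index: int
    p_upper: float
    p_lower: float
    counts_md: ContingencyCounts
    counts_ad: ContingencyCounts
    f_score_md: float = math.nan
    f_score_ad: float = math.nan
    p_enrichment: float = math.nan
    p_enrichment_md_vs_background: float = math.nan
    p_enrichment_ad_vs_background: float = math.nan
    n_derived_risk_md: int = 0
    n_derived_protective_md: int = 0
    n_derived_risk_ad: int = 0
    n_derived_protective_ad: int = 0
    ratio_md: float = math.nan
    ratio_ad: float = math.nan
    p_ratio: float = math.nan


@dataclass(frozen=True)
class PruneConfig:
    """LD pruning parameters: 1 Mb window, r^2 > 0.2 flags a pair."""

    window_bp: int = 1_000_000
    r2_threshold: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")
        if not 0.0 < self.r2_threshold < 1.0:
            raise ValueError("r2_threshold must lie in (0, 1)")


@dataclass(frozen=True)
class PruneResult:
    retained: frozenset
    removed: frozenset
    n_pairs_flagged: int
    seed: int
    n_untested: int = 0


@dataclass
class ReadReport:
    """Row accounting for one reader: accepted + rejected = input rows."""

    n_rows: int = 0
    n_accepted: int = 0
    reject_reasons: dict = field(default_factory=dict)

    @property
    def n_rejected(self) -> int:
        return sum(self.reject_reasons.values())

    def as_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_accepted": self.n_accepted,
            "n_rejected": self.n_rejected,
            "reject_reasons": dict(sorted(self.reject_reasons.items())),
        }


@dataclass
class JoinReport:
    n_gwas: int = 0
    n_joined_md: int = 0
    n_joined_ad: int = 0
    n_unjoined: int = 0
    n_conflicts: int = 0

    def as_dict(self) -> dict:
        return {
            "n_gwas": self.n_gwas,
            "n_joined_md": self.n_joined_md,
            "n_joined_ad": self.n_joined_ad,
            "n_unjoined": self.n_unjoined,
            "n_conflicts": self.n_conflicts,
        }
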
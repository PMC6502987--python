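"""Enrichment and polarity-ratio analysis of an annotated GWAS SNP set.

`EnrichmentAnalysis` is the model object: it holds the annotated SNP table
and the analysis settings (bin construction, F-score convention, MAF
filter). `fit()` performs the decile binning, per-bin fold-change scores,
derived-risk/derived-protective ratios and the MD-vs-AD Fisher contrasts,
returning an `EnrichmentResults` with a summary() table.

The per-bin MD-vs-AD membership contrast uses the table
[[d_MD, c - d_MD], [d_AD, c - d_AD]]; each lineage is additionally
contrasted against the genome background. Three "overall" statistics are
reported because the aggregate can be defined several ways: the bin-pooled
MD-vs-AD Fisher test (default), Fisher-combined per-bin p-values, and a
per-lineage chi-square goodness-of-fit of bin counts d_i against the
expectation c_i * b / a.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import bin_results_frame
from .stats import BinPartition, FisherResult, fisher_exact_2x2, fscore, make_bins
from .types import (
    BinResult,
    ContingencyCounts,
    LINEAGE_AD,
    LINEAGE_MD,
    LINEAGES,
    POLARITY_DERIVED_PROTECTIVE,
    POLARITY_DERIVED_RISK,
)

__all__ = [
    "EnrichmentAnalysis",
    "EnrichmentResults",
    "enrichment_by_bin",
    "ratio_by_bin",
    "overall_contrast",
]


def _counts_by_bin(df: pd.DataFrame, partition: BinPartition):
    bins = partition.assign(df["p_value"].to_numpy())
    c = np.bincount(bins, minlength=partition.n_bins)
    d = {
        lin: np.bincount(bins[(df["lineage"] == lin).to_numpy()], minlength=partition.n_bins)
        for lin in LINEAGES
    }
    return bins, c, d


def enrichment_by_bin(universe: pd.DataFrame, partition: BinPartition, convention: str = "printed"):
    """Per-bin contingency counts, F-scores and MD-vs-AD membership tests.

    ``universe`` is the analyzed (pruned, MAF-filtered) SNP set: columns
    p_value and lineage (NA for SNPs outside catalog sites). Denominators
    a and b are computed on this same universe, so bin counts conserve
    (sum of d over bins = b, sum of c = a) by construction.
    """
    _, c, d = _counts_by_bin(universe, partition)
    a = int(len(universe))
    b = {lin: int((universe["lineage"] == lin).sum()) for lin in LINEAGES}
    results = []
    for i in range(partition.n_bins):
        counts = {
            lin: ContingencyCounts(a=a, b=b[lin], c=int(c[i]), d=int(d[lin][i]))
            for lin in LINEAGES
        }
        r = BinResult(
            bin_index=i,
            p_upper=partition.upper(i),
            p_lower=partition.lower(i),
            counts_md=counts[LINEAGE_MD],
            counts_ad=counts[LINEAGE_AD],
            f_score_md=fscore(counts[LINEAGE_MD], convention),
            f_score_ad=fscore(counts[LINEAGE_AD], convention),
        )
        if c[i] > 0:
            d_md, d_ad = int(d[LINEAGE_MD][i]), int(d[LINEAGE_AD][i])
            r.p_enrichment = fisher_exact_2x2(
                [[d_md, int(c[i]) - d_md], [d_ad, int(c[i]) - d_ad]]
            ).p_value
            for lin in LINEAGES:
                cc = counts[lin]
                p = fisher_exact_2x2(
                    [[cc.d, cc.c - cc.d], [cc.b - cc.d, (cc.a - cc.c) - (cc.b - cc.d)]]
                ).p_value
                setattr(r, f"p_enrichment_{lin.lower()}_vs_background", p)
        results.append(r)
    return results


def ratio_by_bin(resolved: pd.DataFrame, partition: BinPartition, bin_results=None):
    """Per-bin derived-risk : derived-protective counts, ratios and tests.

    ``resolved`` holds polarity-resolved site SNPs only (columns p_value,
    lineage, polarity). Fills and returns ``bin_results`` when given (the
    usual path, so enrichment and ratio live on one BinResult), otherwise
    builds stand-alone results whose contingency counts describe the
    resolved set itself.
    """
    if bin_results is None:
        _, c, d = _counts_by_bin(resolved, partition)
        a = int(len(resolved))
        b = {lin: int((resolved["lineage"] == lin).sum()) for lin in LINEAGES}
        bin_results = [
            BinResult(
                bin_index=i,
                p_upper=partition.upper(i),
                p_lower=partition.lower(i),
                counts_md=ContingencyCounts(a, b[LINEAGE_MD], int(c[i]), int(d[LINEAGE_MD][i])),
                counts_ad=ContingencyCounts(a, b[LINEAGE_AD], int(c[i]), int(d[LINEAGE_AD][i])),
            )
            for i in range(partition.n_bins)
        ]
    bins = partition.assign(resolved["p_value"].to_numpy())
    for i, r in enumerate(bin_results):
        in_bin = bins == i
        tallies = {}
        for lin in LINEAGES:
            lin_mask = in_bin & (resolved["lineage"] == lin).to_numpy()
            n_risk = int((resolved["polarity"].to_numpy()[lin_mask] == POLARITY_DERIVED_RISK).sum())
            n_prot = int(
                (resolved["polarity"].to_numpy()[lin_mask] == POLARITY_DERIVED_PROTECTIVE).sum()
            )
            tallies[lin] = (n_risk, n_prot)
            suffix = lin.lower()
            setattr(r, f"n_derived_risk_{suffix}", n_risk)
            setattr(r, f"n_derived_protective_{suffix}", n_prot)
            setattr(r, f"ratio_{suffix}", n_risk / n_prot if n_prot else math.nan)
        (rk_md, pt_md), (rk_ad, pt_ad) = tallies[LINEAGE_MD], tallies[LINEAGE_AD]
        if rk_md + pt_md > 0 and rk_ad + pt_ad > 0:
            r.p_ratio = fisher_exact_2x2([[rk_md, pt_md], [rk_ad, pt_ad]]).p_value
    return bin_results


def overall_contrast(bin_results, kind: str = "enrichment") -> FisherResult:
    """Pooled MD-vs-AD Fisher test on the bin-summed 2x2 table.

    ``enrichment`` pools site-membership counts [d, c - d] over bins;
    ``ratio`` pools the derived-risk/derived-protective counts.
    """
    if kind == "enrichment":
        md = [sum(r.counts_md.d for r in bin_results), sum(r.counts_md.c - r.counts_md.d for r in bin_results)]
        ad = [sum(r.counts_ad.d for r in bin_results), sum(r.counts_ad.c - r.counts_ad.d for r in bin_results)]
    elif kind == "ratio":
        md = [sum(r.n_derived_risk_md for r in bin_results), sum(r.n_derived_protective_md for r in bin_results)]
        ad = [sum(r.n_derived_risk_ad for r in bin_results), sum(r.n_derived_protective_ad for r in bin_results)]
    else:
        raise ValueError(f"unknown contrast kind: {kind!r}")
    return fisher_exact_2x2([md, ad])


def _combine_defined(pvals):
    p = [x for x in pvals if not math.isnan(x)]
    if not p:
        return math.nan
    return float(sps.combine_pvalues(np.clip(p, 1e-300, 1.0), method="fisher").pvalue)


class EnrichmentAnalysis:
    """Model: enrichment of GWAS SNPs in human-specific sites by p-value bin.

    Parameters
    ----------
    annotated : DataFrame
        Annotated SNP table (see :mod:`archaicsel.io`): the GWAS schema plus
        lineage, ancestral/derived alleles, maf, polarity and
        exclusion_reason columns. Rows with an exclusion_reason are dropped
        from the analysis universe.
    n_bins, bin_mode, edges
        Bin construction; empirical sample deciles by default, or fixed
        user edges (``stats.PAPER_DECILE_EDGES`` replicates the published
        schizophrenia bin boundaries).
    fscore_convention : {"printed", "obs_exp"}
        Orientation of the fold-change score; the two are reciprocals.
    maf_threshold : float or None
        Strict MAF ceiling (default 0.1); None disables the filter.
    maf_filter_scope : {"both", "enrichment_only"}
        Whether the MAF filter also restricts the polarity-ratio analysis.
    """

    def __init__(
        self,
        annotated: pd.DataFrame,
        *,
        n_bins: int = 10,
        bin_mode: str = "empirical",
        edges=None,
        fscore_convention: str = "printed",
        maf_threshold: float | None = 0.1,
        maf_filter_scope: str = "both",
    ) -> None:
        if maf_filter_scope not in ("both", "enrichment_only"):
            raise ValueError("maf_filter_scope must be 'both' or 'enrichment_only'")
        if fscore_convention not in ("printed", "obs_exp"):
            raise ValueError("fscore_convention must be 'printed' or 'obs_exp'")
        self.annotated = annotated
        self.n_bins = n_bins
        self.bin_mode = bin_mode
        self.edges = edges
        self.fscore_convention = fscore_convention
        self.maf_threshold = maf_threshold
        self.maf_filter_scope = maf_filter_scope

    def fit(self) -> "EnrichmentResults":
        base = self.annotated.loc[self.annotated["exclusion_reason"].isna()]
        if self.maf_threshold is not None:
            universe = base.loc[base["maf"] < self.maf_threshold]
        else:
            universe = base
        partition = make_bins(
            universe["p_value"].to_numpy(), n_bins=self.n_bins, mode=self.bin_mode, edges=self.edges
        )
        bin_results = enrichment_by_bin(universe, partition, self.fscore_convention)

        ratio_universe = universe if self.maf_filter_scope == "both" else base
        resolved_mask = ratio_universe["polarity"].isin(
            [POLARITY_DERIVED_RISK, POLARITY_DERIVED_PROTECTIVE]
        )
        resolved = ratio_universe.loc[resolved_mask]
        bin_results = ratio_by_bin(resolved, partition, bin_results)

        a = int(len(universe))
        b = {lin: int((universe["lineage"] == lin).sum()) for lin in LINEAGES}
        gof = {}
        for lin in LINEAGES:
            counts = [getattr(r, f"counts_{lin.lower()}") for r in bin_results]
            observed = np.array([cc.d for cc in counts], dtype=float)
            expected = np.array([cc.c * b[lin] / a if a else 0.0 for cc in counts])
            if b[lin] > 0 and (expected > 0).all():
                gof[lin] = float(sps.chisquare(observed, expected).pvalue)
            else:
                gof[lin] = math.nan

        return EnrichmentResults(
            bin_results=bin_results,
            partition=partition,
            fscore_convention=self.fscore_convention,
            maf_threshold=self.maf_threshold,
            maf_filter_scope=self.maf_filter_scope,
            n_analyzed=a,
            n_sites=b,
            n_resolved={
                lin: int((resolved["lineage"] == lin).sum()) for lin in LINEAGES
            },
            overall_enrichment=overall_contrast(bin_results, "enrichment"),
            overall_ratio=overall_contrast(bin_results, "ratio"),
            overall_enrichment_combined=_combine_defined(
                [r.p_enrichment for r in bin_results]
            ),
            overall_ratio_combined=_combine_defined([r.p_ratio for r in bin_results]),
            overall_gof_by_lineage=gof,
        )


@dataclass
class EnrichmentResults:
    """Fitted per-bin and overall enrichment/ratio statistics."""

    bin_results: list
    partition: BinPartition
    fscore_convention: str
    maf_threshold: float | None
    maf_filter_scope: str
    n_analyzed: int
    n_sites: dict
    n_resolved: dict
    overall_enrichment: FisherResult
    overall_ratio: FisherResult
    overall_enrichment_combined: float
    overall_ratio_combined: float
    overall_gof_by_lineage: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """One row per (bin x lineage), the on-disk result schema."""
        return bin_results_frame(self.bin_results)

    def pooled_ratio(self, lineage: str) -> float:
        """Bin-pooled derived-risk : derived-protective ratio for a lineage."""
        suffix = lineage.lower()
        risk = sum(getattr(r, f"n_derived_risk_{suffix}") for r in self.bin_results)
        prot = sum(getattr(r, f"n_derived_protective_{suffix}") for r in self.bin_results)
        return risk / prot if prot else math.nan

    def as_summary_dict(self) -> dict:
        return {
            "fscore_convention": self.fscore_convention,
            "maf_threshold": self.maf_threshold,
            "maf_filter_scope": self.maf_filter_scope,
            "bin_edges": list(self.partition.edges),
            "n_analyzed": self.n_analyzed,
            "n_sites": dict(self.n_sites),
            "n_resolved": dict(self.n_resolved),
            "overall_aggregation_default": "bin_pooled_fisher_md_vs_ad",
            "overall_enrichment_p": self.overall_enrichment.p_value,
            "overall_ratio_p": self.overall_ratio.p_value,
            "overall_enrichment_p_combined_bins": self.overall_enrichment_combined,
            "overall_ratio_p_combined_bins": self.overall_ratio_combined,
            "overall_enrichment_gof_p_by_lineage": dict(self.overall_gof_by_lineage),
        }

    def summary(self) -> str:
        """Human-readable per-bin table plus the overall contrasts."""
        def f(x, width=10):
            if isinstance(x, float) and math.isnan(x):
                return "NA".rjust(width)
            if isinstance(x, float):
                return f"{x:.4g}".rjust(width)
            return str(x).rjust(width)

        lines = [
            "Enrichment of GWAS SNPs in human-specific sites",
            "=" * 78,
            f"analyzed SNPs: {self.n_analyzed}   MD sites: {self.n_sites[LINEAGE_MD]}"
            f"   AD sites: {self.n_sites[LINEAGE_AD]}",
            f"F-score convention: {self.fscore_convention}   MAF < {self.maf_threshold}"
            f" ({self.maf_filter_scope})",
            "-" * 78,
            "bin    p-range          F(MD)      F(AD)     p(enr)  ratio(MD)  ratio(AD)   p(ratio)",
        ]
        for r in self.bin_results:
            rng = f"[{r.p_upper:.3f},{r.p_lower:.3f}]"
            lines.append(
                f"{r.bin_index:>3}  {rng:<15}"
                + f(r.f_score_md)
                + f(r.f_score_ad)
                + f(r.p_enrichment)
                + f(r.ratio_md, 11)
                + f(r.ratio_ad, 11)
                + f(r.p_ratio, 11)
            )
        lines += [
            "-" * 78,
            f"overall MD-vs-AD membership p (pooled bins): {self.overall_enrichment.p_value:.4g}",
            f"overall MD-vs-AD risk:protective p (pooled): {self.overall_ratio.p_value:.4g}",
            f"pooled ratio MD: {f(self.pooled_ratio(LINEAGE_MD)).strip()}   "
            f"AD: {f(self.pooled_ratio(LINEAGE_AD)).strip()}",
        ]
        return "\n".join(lines)
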
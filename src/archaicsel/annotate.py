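"""MAF attachment and filtering, and derived-allele polarity classification.

A site-overlapping GWAS SNP is *derived-risk* when its derived allele (the
non-ancestral one, ancestral state taken from the chimpanzee-referenced
catalog) is the risk allele of the disorder, and *derived-protective* when
the derived allele is the protective allele. The odds ratio is per effect
allele, so OR > 1 makes the effect allele the risk allele and OR < 1 the
other allele.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .types import (
    COMPLEMENT,
    POLARITY_DERIVED_PROTECTIVE,
    POLARITY_DERIVED_RISK,
    POLARITY_UNRESOLVED,
)

logger = logging.getLogger(__name__)


def attach_maf(annotated: pd.DataFrame, maf_table: pd.DataFrame) -> pd.DataFrame:
    """Attach per-SNP MAF; SNPs without an entry are excluded ("no_maf")."""
    out = annotated.copy()
    lookup = maf_table.set_index("snp_id")["maf"]
    out["maf"] = out["snp_id"].map(lookup)
    missing = out["maf"].isna() & out["exclusion_reason"].isna()
    out.loc[missing, "exclusion_reason"] = "no_maf"
    n_missing = int(missing.sum())
    if n_missing:
        logger.warning("%d SNP(s) excluded: no MAF entry", n_missing)
    return out


def maf_filter(annotated: pd.DataFrame, threshold: float = 0.1) -> pd.DataFrame:
    """Retain strictly MAF < threshold (the published filter is strict)."""
    return annotated.loc[annotated["maf"] < threshold].reset_index(drop=True)


def classify_polarity(allele_effect, allele_other, odds_ratio, allele_ancestral):
    """Classify one joined SNP/site pair.

    Returns ``(polarity, reason)`` with polarity one of derived_risk /
    derived_protective / unresolved. Strand handling: the ancestral allele
    is matched against the GWAS alleles directly first; only if that fails
    are both GWAS alleles complemented, and strand-ambiguous SNPs (A/T or
    C/G) are never complement-resolved. OR exactly 1 gives no direction.
    """
    if allele_ancestral == allele_effect:
        derived = allele_other
    elif allele_ancestral == allele_other:
        derived = allele_effect
    else:
        if allele_other == COMPLEMENT[allele_effect]:
            return POLARITY_UNRESOLVED, "strand_ambiguous"
        if allele_ancestral == COMPLEMENT[allele_effect]:
            derived = allele_other
        elif allele_ancestral == COMPLEMENT[allele_other]:
            derived = allele_effect
        else:
            return POLARITY_UNRESOLVED, "allele_mismatch"
    if odds_ratio == 1.0:
        return POLARITY_UNRESOLVED, "no_direction"
    risk = allele_effect if odds_ratio > 1.0 else allele_other
    if derived == risk:
        return POLARITY_DERIVED_RISK, None
    return POLARITY_DERIVED_PROTECTIVE, None


def classify_polarities(annotated: pd.DataFrame) -> pd.DataFrame:
    """Add polarity / polarity_reason columns for site-joined SNPs.

    Non-site SNPs keep NA polarity; unresolved reasons are counted in the
    log. Every joined SNP ends in exactly one of the three polarity states.
    """
    out = annotated.copy()
    out["polarity"] = pd.NA
    out["polarity_reason"] = pd.NA
    joined = out["lineage"].notna() & out["exclusion_reason"].isna()
    idx = np.flatnonzero(joined.to_numpy())
    eff = out["allele_effect"].to_numpy()
    oth = out["allele_other"].to_numpy()
    odds = out["odds_ratio"].to_numpy()
    anc = out["allele_ancestral"].to_numpy()
    pol = np.full(len(out), None, dtype=object)
    reason = np.full(len(out), None, dtype=object)
    for i in idx:
        pol[i], reason[i] = classify_polarity(eff[i], oth[i], odds[i], anc[i])
    out.loc[joined, "polarity"] = pol[idx]
    out.loc[joined, "polarity_reason"] = reason[idx]
    n_unresolved = int((out["polarity"] == POLARITY_UNRESOLVED).sum())
    if n_unresolved:
        reasons = out.loc[out["polarity"] == POLARITY_UNRESOLVED, "polarity_reason"]
        logger.info("polarity unresolved for %d SNP(s): %s", n_unresolved, reasons.value_counts().to_dict())
    return out
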
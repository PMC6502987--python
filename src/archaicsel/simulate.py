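"""Synthetic generators for all four pipeline inputs, with known ground truth.

The generator produces GWAS summary statistics directly (no individual-level
case/control genotypes): the downstream analysis consumes only summary
statistics, and direct generation makes the ground truth exact. It emulates,
at desk scale, a catalog of modern-human-specific (MD) and
archaic-human-specific (AD) sites of which a configurable fraction is
polymorphic in the GWAS, a low-frequency MAF spectrum for site-overlapping
SNPs, a block-structured LD reference panel, and an injectable excess
``theta`` of derived-protective over derived-risk alleles at MD sites
(theta = 1 is the null of symmetric allelic turnover).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io import PanelGenotypes, write_table
from .types import LINEAGE_AD, LINEAGE_MD, POLARITY_DERIVED_PROTECTIVE, POLARITY_DERIVED_RISK

_NONAMBIG_PAIRS = (("A", "C"), ("A", "G"), ("C", "T"), ("G", "T"))
_ALL_PAIRS = _NONAMBIG_PAIRS + (("A", "T"), ("C", "G"))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults are a scaled-down rendition of the published study: ~30% of
    catalog sites polymorphic in the GWAS, site-SNP MAF below 0.1, block
    LD at r^2 ~ 0.8, a 5% true-effect fraction, and the symmetric-polarity
    null (theta = 1) for both lineages. ``protective_excess_md`` is theta,
    the factor by which derived-protective outnumber derived-risk alleles
    among MD-site SNPs.
    """

    n_snps: int = 20_000
    n_md_sites: int = 4_000
    n_ad_sites: int = 3_000
    overlap_fraction: float = 0.3
    n_samples_panel: int = 200
    n_ld_blocks: int = 5_000
    within_block_r2: float = 0.8
    maf_beta_params: tuple = (0.5, 3.0)
    protective_excess_md: float = 1.0
    protective_excess_ad: float = 1.0
    assoc_effect_fraction: float = 0.05
    seed: int = 0
    # mechanics below: locations, effect-size scale, optional couplings
    chrom: str = "1"
    block_spacing_bp: int = 50_000
    snp_spacing_bp: int = 500
    effect_z: float = 2.5
    or_log_sd: float = 0.15
    coupling_gamma: float = 0.0
    cap_site_maf: bool = True
    site_rsid_fraction: float = 0.7

    def __post_init__(self) -> None:
        if min(self.n_snps, self.n_md_sites, self.n_ad_sites, self.n_ld_blocks) <= 0:
            raise ValueError("all counts must be positive")
        if not 0.0 < self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must lie in (0, 1]")
        if self.protective_excess_md < 1.0 or self.protective_excess_ad < 1.0:
            raise ValueError("protective excess theta must be >= 1")
        if self.n_samples_panel < 4:
            raise ValueError("need at least 4 panel samples")
        if not 0.0 <= self.within_block_r2 <= 1.0:
            raise ValueError("within_block_r2 must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Per-SNP truth for the generated GWAS set."""

    polarity: np.ndarray  # "" for non-site SNPs
    lineage: np.ndarray  # "" for non-site SNPs
    block: np.ndarray
    counts: dict = field(default_factory=dict)
    realized_theta: dict = field(default_factory=dict)


@dataclass
class SimData:
    gwas: pd.DataFrame
    sites: pd.DataFrame
    maf: pd.DataFrame
    panel: PanelGenotypes
    truth: GroundTruth
    config: SimConfig


def _positions(config: SimConfig):
    """SNP coordinates and block ids: blocks laid out along one chromosome."""
    per_block = np.full(config.n_ld_blocks, config.n_snps // config.n_ld_blocks)
    per_block[: config.n_snps % config.n_ld_blocks] += 1
    span = int(per_block.max()) * config.snp_spacing_bp
    if span >= config.block_spacing_bp:
        raise ValueError("blocks overlap: increase block_spacing_bp or snp_spacing_bp")
    pos, block = [], []
    for i, k in enumerate(per_block):
        base = 1 + i * config.block_spacing_bp
        pos.extend(base + j * config.snp_spacing_bp for j in range(k))
        block.extend([i] * int(k))
    return np.array(pos, dtype=np.int64), np.array(block, dtype=np.int64)


def simulate_panel(config: SimConfig, rng: np.random.Generator | None = None):
    """Generate the LD reference panel: block-copied dosages with noise.

    Within a block every site copies one latent dosage vector and, with
    probability 1 - within_block_r2**(1/4) per sample, redraws
    independently; pairwise dosage correlations then satisfy
    r^2 ~ within_block_r2 inside a block and vanish across blocks.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    pos, block = _positions(config)
    n = len(pos)
    q = config.within_block_r2 ** 0.25
    dosages = np.empty((n, config.n_samples_panel), dtype=np.int8)
    for b in range(config.n_ld_blocks):
        idx = np.flatnonzero(block == b)
        freq = rng.uniform(0.15, 0.85)
        latent = rng.binomial(2, freq, config.n_samples_panel)
        for i in idx:
            keep = rng.random(config.n_samples_panel) < q
            fresh = rng.binomial(2, freq, config.n_samples_panel)
            dosages[i] = np.where(keep, latent, fresh)
    panel = PanelGenotypes(
        chrom=np.array([config.chrom] * n, dtype=object),
        pos=pos,
        ref=np.array(["A"] * n, dtype=object),
        alt=np.array(["G"] * n, dtype=object),
        dosages=dosages,
    )
    return panel, block


def _truncated_beta(rng, a, b, size, upper=0.5):
    """Beta(a, b) resampled into (0, upper]."""
    x = rng.beta(a, b, size)
    bad = (x <= 0) | (x > upper)
    while bad.any():
        x[bad] = rng.beta(a, b, int(bad.sum()))
        bad = (x <= 0) | (x > upper)
    return x


def simulate_catalog_and_gwas(config: SimConfig, panel: PanelGenotypes, block=None, rng=None) -> SimData:
    """Generate the site catalog, GWAS summary statistics, MAF table and truth.

    ``overlap_fraction`` of catalog sites coincide with GWAS SNP positions;
    the remainder are monomorphic in the GWAS (positions outside it). For an
    overlapped site the polarity is derived-protective with probability
    theta/(1+theta) and the odds ratio is drawn so the derived allele's
    direction matches the drawn polarity. Null SNPs get uniform p-values;
    effect SNPs get p-values from a shifted-|z| alternative. By default
    polarity is drawn independently of the p-value so any detected polarity
    signal is attributable to the injected theta; ``coupling_gamma > 0``
    concentrates the excess in low-p bins (theta_eff = theta**((1-p)**gamma)).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n = len(panel)
    if block is None:
        block = np.zeros(n, dtype=np.int64)
    n_overlap_md = round(config.n_md_sites * config.overlap_fraction)
    n_overlap_ad = round(config.n_ad_sites * config.overlap_fraction)
    if n_overlap_md + n_overlap_ad > n:
        raise ValueError("more overlapping sites requested than GWAS SNPs available")

    chrom = panel.chrom
    pos = panel.pos
    snp_ids = np.array([f"rs{i + 1}" for i in range(n)], dtype=object)

    # p-values: uniform null, shifted-|z| alternative
    is_effect = rng.random(n) < config.assoc_effect_fraction
    p_values = rng.uniform(0.0, 1.0, n)
    n_eff = int(is_effect.sum())
    if n_eff:
        z = rng.normal(config.effect_z, 1.0, n_eff)
        p_values[is_effect] = 2.0 * norm.sf(np.abs(z))

    # which SNPs coincide with catalog sites, and their lineage
    overlap_idx = rng.choice(n, size=n_overlap_md + n_overlap_ad, replace=False)
    md_idx = overlap_idx[:n_overlap_md]
    ad_idx = overlap_idx[n_overlap_md:]
    lineage = np.full(n, "", dtype=object)
    lineage[md_idx] = LINEAGE_MD
    lineage[ad_idx] = LINEAGE_AD
    is_site = lineage != ""

    # alleles: site SNPs use strand-unambiguous pairs so polarity is always
    # resolvable; non-site SNPs may be A/T or C/G
    allele_a = np.empty(n, dtype=object)
    allele_b = np.empty(n, dtype=object)
    pair_site = rng.integers(0, len(_NONAMBIG_PAIRS), n)
    pair_any = rng.integers(0, len(_ALL_PAIRS), n)
    for i in range(n):
        a1, a2 = _NONAMBIG_PAIRS[pair_site[i]] if is_site[i] else _ALL_PAIRS[pair_any[i]]
        allele_a[i], allele_b[i] = a1, a2
    ancestral_is_a = rng.random(n) < 0.5
    ancestral = np.where(ancestral_is_a, allele_a, allele_b)
    derived = np.where(ancestral_is_a, allele_b, allele_a)

    # polarity of site SNPs and matched odds ratios
    theta = np.ones(n)
    theta[md_idx] = config.protective_excess_md
    theta[ad_idx] = config.protective_excess_ad
    if config.coupling_gamma > 0:
        theta = theta ** ((1.0 - p_values) ** config.coupling_gamma)
    prob_protective = theta / (1.0 + theta)
    is_protective = rng.random(n) < prob_protective
    polarity = np.full(n, "", dtype=object)
    polarity[is_site & is_protective] = POLARITY_DERIVED_PROTECTIVE
    polarity[is_site & ~is_protective] = POLARITY_DERIVED_RISK

    magnitude = np.exp(np.abs(rng.normal(0.0, config.or_log_sd, n)))
    effect_is_derived = rng.random(n) < 0.5
    allele_effect = np.where(effect_is_derived, derived, ancestral)
    allele_other = np.where(effect_is_derived, ancestral, derived)
    # risk allele is derived iff polarity is derived_risk
    risk_is_derived = polarity == POLARITY_DERIVED_RISK
    effect_is_risk = np.where(is_site, effect_is_derived == risk_is_derived, rng.random(n) < 0.5)
    odds_ratio = np.where(effect_is_risk, magnitude, 1.0 / magnitude)

    # MAF spectrum; site SNPs occur at low frequency
    a_beta, b_beta = config.maf_beta_params
    maf = _truncated_beta(rng, a_beta, b_beta, n)
    if config.cap_site_maf:
        site = np.flatnonzero(is_site)
        bad = site[maf[site] >= 0.1]
        while bad.size:
            maf[bad] = rng.beta(a_beta, b_beta, bad.size)
            keep = (maf[bad] > 0) & (maf[bad] < 0.1)
            bad = bad[~keep]

    gwas = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": chrom,
            "pos": pos,
            "allele_effect": allele_effect,
            "allele_other": allele_other,
            "odds_ratio": odds_ratio,
            "p_value": p_values,
        }
    )

    # catalog: overlapped sites at GWAS coordinates (rsID present for a
    # fraction, exercising both join keys) plus monomorphic remainder
    site_rows = []
    has_rsid = rng.random(n) < config.site_rsid_fraction
    for i in np.sort(overlap_idx):
        site_rows.append(
            (chrom[i], int(pos[i]), snp_ids[i] if has_rsid[i] else "", ancestral[i], derived[i], lineage[i])
        )
    n_mono_md = config.n_md_sites - n_overlap_md
    n_mono_ad = config.n_ad_sites - n_overlap_ad
    mono_base = int(pos.max()) + 1_000_000
    for j in range(n_mono_md + n_mono_ad):
        anc, der = _NONAMBIG_PAIRS[int(rng.integers(0, len(_NONAMBIG_PAIRS)))]
        site_rows.append(
            (
                config.chrom,
                mono_base + j * 1000,
                f"cs{j + 1}",
                anc,
                der,
                LINEAGE_MD if j < n_mono_md else LINEAGE_AD,
            )
        )
    sites = pd.DataFrame(
        site_rows,
        columns=["chrom", "pos", "snp_id", "allele_ancestral", "allele_derived", "lineage"],
    ).sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)

    maf_table = pd.DataFrame({"snp_id": snp_ids, "maf": maf})

    # exact alleles into the panel (REF = ancestral, ALT = derived)
    panel.ref[:] = ancestral
    panel.alt[:] = derived

    counts = {
        lin: {
            "risk": int(((lineage == lin) & (polarity == POLARITY_DERIVED_RISK)).sum()),
            "protective": int(
                ((lineage == lin) & (polarity == POLARITY_DERIVED_PROTECTIVE)).sum()
            ),
        }
        for lin in (LINEAGE_MD, LINEAGE_AD)
    }
    realized_theta = {
        lin: (c["protective"] / c["risk"] if c["risk"] else float("nan"))
        for lin, c in counts.items()
    }
    truth = GroundTruth(
        polarity=polarity,
        lineage=lineage,
        block=block,
        counts=counts,
        realized_theta=realized_theta,
    )
    return SimData(gwas=gwas, sites=sites, maf=maf_table, panel=panel, truth=truth, config=config)


def simulate(config: SimConfig) -> SimData:
    """Generate a full synthetic dataset (panel + catalog + GWAS + MAF)."""
    rng = np.random.default_rng(config.seed)
    panel, block = simulate_panel(config, rng)
    return simulate_catalog_and_gwas(config, panel, block=block, rng=rng)


def write_inputs(sim: SimData, outdir) -> dict:
    """Write the generated inputs in the exact dialects the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "gwas": outdir / "gwas.tsv",
        "sites": outdir / "sites.tsv",
        "maf": outdir / "maf.tsv",
        "panel": outdir / "panel.vcf",
    }
    write_table(sim.gwas, paths["gwas"])
    write_table(sim.sites, paths["sites"])
    write_table(sim.maf, paths["maf"])
    sim.panel.to_vcf(paths["panel"])
    return paths


def simulate_resolved_polarities(
    n_md: int,
    n_ad: int,
    theta_md: float = 1.0,
    theta_ad: float = 1.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Directly generate polarity-resolved site SNPs (lineage, polarity, p).

    A summary-level shortcut for calibration and power studies of the ratio
    analysis: each SNP is derived-protective with probability
    theta/(1+theta) for its lineage and carries an independent uniform
    p-value, exactly the sampling model the full generator induces for
    resolved site SNPs under default (uncoupled) settings.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    lineage = np.array([LINEAGE_MD] * n_md + [LINEAGE_AD] * n_ad, dtype=object)
    theta = np.where(lineage == LINEAGE_MD, theta_md, theta_ad)
    protective = rng.random(n_md + n_ad) < theta / (1.0 + theta)
    polarity = np.where(protective, POLARITY_DERIVED_PROTECTIVE, POLARITY_DERIVED_RISK)
    return pd.DataFrame(
        {
            "lineage": lineage,
            "polarity": polarity,
            "p_value": rng.uniform(0.0, 1.0, n_md + n_ad),
        }
    )
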
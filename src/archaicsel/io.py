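"""Readers, writers and the join step for the pipeline's tabular inputs.

Canonical in-memory schemas (pandas DataFrames):

* GWAS summary statistics — columns ``snp_id, chrom, pos, allele_effect,
  allele_other, odds_ratio, p_value``. One row per biallelic SNV; the odds
  ratio is per effect allele.
* Human-specific site catalog — columns ``chrom, pos, snp_id,
  allele_ancestral, allele_derived, lineage`` with lineage ``MD``
  (modern-human-specific) or ``AD`` (archaic-human-specific).
* MAF table — columns ``snp_id, maf`` with maf in [0, 0.5].
* Annotated SNPs — the GWAS schema plus ``lineage, allele_ancestral,
  allele_derived, maf, polarity, polarity_reason, exclusion_reason``.

All on-disk tables are tab-delimited with a header, ``NA`` for missing, and
fixed column order; floats are written with ``repr`` so a write/read
round-trip is exact.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    JoinReport,
    LINEAGE_AD,
    LINEAGE_MD,
    LINEAGES,
    NUCLEOTIDES,
    ReadReport,
)

logger = logging.getLogger(__name__)

GWAS_COLUMNS = [
    "snp_id",
    "chrom",
    "pos",
    "allele_effect",
    "allele_other",
    "odds_ratio",
    "p_value",
]
SITE_COLUMNS = ["chrom", "pos", "snp_id", "allele_ancestral", "allele_derived", "lineage"]
MAF_COLUMNS = ["snp_id", "maf"]

#: Column-name mapping for PGC-style ("daner") summary-statistic headers.
DANER_DIALECT = {
    "snp_id": "SNP",
    "chrom": "CHR",
    "pos": "BP",
    "allele_effect": "A1",
    "allele_other": "A2",
    "odds_ratio": "OR",
    "p_value": "P",
}

RESULT_COLUMNS = [
    "bin_index",
    "p_upper",
    "p_lower",
    "lineage",
    "a",
    "b",
    "c",
    "d",
    "f_score",
    "p_enrichment",
    "p_vs_background",
    "n_derived_risk",
    "n_derived_protective",
    "ratio",
    "p_ratio",
]

ANNOTATED_COLUMNS = GWAS_COLUMNS + [
    "lineage",
    "allele_ancestral",
    "allele_derived",
    "maf",
    "polarity",
    "polarity_reason",
    "exclusion_reason",
]


def _read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def _is_valid_allele(series: pd.Series) -> pd.Series:
    return series.isin(sorted(NUCLEOTIDES))


def _reject(report: ReadReport, mask: pd.Series, reason: str, already: pd.Series):
    """Count `reason` for rows newly failing; return updated cumulative mask."""
    fresh = mask & ~already
    n = int(fresh.sum())
    if n:
        report.reject_reasons[reason] = report.reject_reasons.get(reason, 0) + n
        logger.warning("rejected %d row(s): %s", n, reason)
    return already | mask


def read_gwas(path, dialect: dict | None = None):
    """Read GWAS summary statistics.

    Parameters
    ----------
    path : str or Path
        Tab-delimited file with a header.
    dialect : dict, optional
        Mapping from canonical column names to the file's column names
        (e.g. :data:`DANER_DIALECT`). Default assumes canonical names.

    Returns
    -------
    (DataFrame, ReadReport)
        Validated records (canonical schema) and row accounting. Rows with
        malformed alleles (including indels / multi-allelic notation), a
        non-positive or unparseable odds ratio, a p-value outside [0, 1], or
        a duplicated key are rejected, not fatal; a missing mandatory column
        is a hard error.
    """
    raw = _read_table(path)
    mapping = {canon: (dialect or {}).get(canon, canon) for canon in GWAS_COLUMNS}
    missing = [src for src in mapping.values() if src not in raw.columns]
    if missing:
        raise ValueError(f"GWAS input is missing mandatory column(s): {missing}")
    df = pd.DataFrame({canon: raw[src] for canon, src in mapping.items()})
    report = ReadReport(n_rows=len(df))

    df["allele_effect"] = df["allele_effect"].str.upper()
    df["allele_other"] = df["allele_other"].str.upper()
    pos = pd.to_numeric(df["pos"], errors="coerce")
    odds = pd.to_numeric(df["odds_ratio"], errors="coerce")
    pval = pd.to_numeric(df["p_value"], errors="coerce")

    bad = pd.Series(False, index=df.index)
    bad = _reject(report, pos.isna() | (pos < 1), "bad_position", bad)
    bad = _reject(
        report,
        ~_is_valid_allele(df["allele_effect"]) | ~_is_valid_allele(df["allele_other"]),
        "bad_allele",
        bad,
    )
    bad = _reject(report, df["allele_effect"] == df["allele_other"], "same_alleles", bad)
    bad = _reject(report, odds.isna() | (odds <= 0), "bad_odds_ratio", bad)
    bad = _reject(report, pval.isna() | (pval < 0) | (pval > 1), "bad_p_value", bad)
    bad = _reject(
        report, df.duplicated(subset=["chrom", "pos"], keep="first"), "duplicate_position", bad
    )
    bad = _reject(report, df.duplicated(subset=["snp_id"], keep="first"), "duplicate_id", bad)

    out = df.loc[~bad].copy()
    out["pos"] = pos.loc[~bad].astype(np.int64)
    out["odds_ratio"] = odds.loc[~bad].astype(float)
    out["p_value"] = pval.loc[~bad].astype(float)
    out = out.reset_index(drop=True)
    report.n_accepted = len(out)
    return out, report


def read_site_catalog(path):
    """Read the human-specific site catalog (MD/AD lineage classes).

    Returns ``(DataFrame, ReadReport)``; per-lineage counts are logged.
    Rows with a lineage outside {MD, AD}, identical ancestral and derived
    alleles, malformed alleles, or a duplicated position are rejected.
    """
    df = _read_table(path)
    missing = [c for c in SITE_COLUMNS if c not in df.columns and c != "snp_id"]
    if missing:
        raise ValueError(f"site catalog is missing mandatory column(s): {missing}")
    if "snp_id" not in df.columns:
        df["snp_id"] = ""
    df = df[SITE_COLUMNS].copy()
    report = ReadReport(n_rows=len(df))
    if len(df) == 0:
        logger.warning("site catalog %s is empty", path)
        return df.assign(pos=pd.Series(dtype=np.int64)), report

    df["allele_ancestral"] = df["allele_ancestral"].str.upper()
    df["allele_derived"] = df["allele_derived"].str.upper()
    df["lineage"] = df["lineage"].str.upper()
    pos = pd.to_numeric(df["pos"], errors="coerce")

    bad = pd.Series(False, index=df.index)
    bad = _reject(report, pos.isna() | (pos < 1), "bad_position", bad)
    bad = _reject(report, ~df["lineage"].isin(LINEAGES), "bad_lineage", bad)
    bad = _reject(
        report,
        ~_is_valid_allele(df["allele_ancestral"]) | ~_is_valid_allele(df["allele_derived"]),
        "bad_allele",
        bad,
    )
    bad = _reject(
        report, df["allele_ancestral"] == df["allele_derived"], "ancestral_equals_derived", bad
    )
    bad = _reject(
        report, df.duplicated(subset=["chrom", "pos"], keep="first"), "duplicate_position", bad
    )
    nonempty = df["snp_id"] != ""
    bad = _reject(
        report,
        nonempty & df.duplicated(subset=["snp_id"], keep="first") & nonempty,
        "duplicate_id",
        bad,
    )

    out = df.loc[~bad].copy()
    out["pos"] = pos.loc[~bad].astype(np.int64)
    out = out.reset_index(drop=True)
    report.n_accepted = len(out)
    counts = out["lineage"].value_counts().to_dict()
    logger.info(
        "site catalog: %d MD, %d AD sites accepted",
        counts.get(LINEAGE_MD, 0),
        counts.get(LINEAGE_AD, 0),
    )
    return out, report


def read_maf(path):
    """Read the minor-allele-frequency table.

    Exact duplicate rows are accepted once; a repeated snp_id with a
    conflicting value rejects the later row. MAF must lie in [0, 0.5].
    """
    df = _read_table(path)
    missing = [c for c in MAF_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"MAF table is missing mandatory column(s): {missing}")
    df = df[MAF_COLUMNS].copy()
    report = ReadReport(n_rows=len(df))
    maf = pd.to_numeric(df["maf"], errors="coerce")

    bad = pd.Series(False, index=df.index)
    bad = _reject(report, maf.isna() | (maf < 0) | (maf > 0.5), "bad_maf", bad)
    exact_dup = df.duplicated(subset=MAF_COLUMNS, keep="first")
    id_dup = df.duplicated(subset=["snp_id"], keep="first")
    bad = _reject(report, exact_dup, "duplicate_row", bad)
    bad = _reject(report, id_dup & ~exact_dup, "conflicting_maf", bad)

    out = df.loc[~bad].copy()
    out["maf"] = maf.loc[~bad].astype(float)
    out = out.reset_index(drop=True)
    report.n_accepted = len(out)
    return out, report


def join_sites(gwas: pd.DataFrame, sites: pd.DataFrame):
    """Join GWAS SNPs to catalog sites by rsID first, then by (chrom, pos).

    Every GWAS SNP is kept in the returned frame (it remains the genome-wide
    denominator of the enrichment analysis); joined rows carry ``lineage``
    and the ancestral/derived alleles, unjoined rows carry NA. A SNP whose
    rsID matches a site recorded at different coordinates is excluded with
    ``exclusion_reason = "key_conflict"`` rather than joined by either key.
    """
    out = gwas.copy().reset_index(drop=True)
    for col in ("lineage", "allele_ancestral", "allele_derived"):
        out[col] = pd.NA
    out["exclusion_reason"] = pd.NA

    site_cols = ["chrom", "pos", "allele_ancestral", "allele_derived", "lineage"]
    by_id = (
        sites.loc[sites["snp_id"] != ""].set_index("snp_id")[site_cols]
        if len(sites)
        else pd.DataFrame(columns=site_cols)
    )
    by_coord = sites.set_index(["chrom", "pos"])[site_cols[2:]] if len(sites) else None

    report = JoinReport(n_gwas=len(out))
    id_hit = out["snp_id"].isin(by_id.index) if len(by_id) else pd.Series(False, index=out.index)
    if id_hit.any():
        matched = by_id.loc[out.loc[id_hit, "snp_id"]]
        same_coord = (matched["chrom"].to_numpy() == out.loc[id_hit, "chrom"].to_numpy()) & (
            matched["pos"].to_numpy() == out.loc[id_hit, "pos"].to_numpy()
        )
        hit_idx = out.index[id_hit]
        ok_idx = hit_idx[same_coord]
        conflict_idx = hit_idx[~same_coord]
        out.loc[ok_idx, ["allele_ancestral", "allele_derived", "lineage"]] = matched.loc[
            same_coord, ["allele_ancestral", "allele_derived", "lineage"]
        ].to_numpy()
        out.loc[conflict_idx, "exclusion_reason"] = "key_conflict"
        report.n_conflicts = len(conflict_idx)
        if report.n_conflicts:
            logger.warning("%d SNP(s) excluded: rsID/coordinate key conflict", report.n_conflicts)

    if by_coord is not None and len(by_coord):
        remaining = out["lineage"].isna() & out["exclusion_reason"].isna()
        keys = pd.MultiIndex.from_frame(out.loc[remaining, ["chrom", "pos"]])
        coord_hit = keys.isin(by_coord.index)
        rem_idx = out.index[remaining][coord_hit]
        if len(rem_idx):
            matched = by_coord.loc[keys[coord_hit]]
            out.loc[rem_idx, ["allele_ancestral", "allele_derived", "lineage"]] = (
                matched.to_numpy()
            )

    report.n_joined_md = int((out["lineage"] == LINEAGE_MD).sum())
    report.n_joined_ad = int((out["lineage"] == LINEAGE_AD).sum())
    report.n_unjoined = int(out["lineage"].isna().sum())
    logger.info(
        "join: %d MD, %d AD, %d unjoined, %d conflicts",
        report.n_joined_md,
        report.n_joined_ad,
        report.n_unjoined,
        report.n_conflicts,
    )
    return out, report


def _fmt(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, float):
        if math.isnan(value):
            return "NA"
        return repr(float(value))
    if pd.isna(value):
        return "NA"
    return str(value)


def write_table(df: pd.DataFrame, path) -> None:
    """Write a DataFrame as TSV with the ``NA`` sentinel and exact floats."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(df.columns) + "\n")
        for row in df.itertuples(index=False):
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def bin_results_frame(results) -> pd.DataFrame:
    """Flatten a sequence of BinResult into the on-disk result schema."""
    rows = []
    for r in results:
        for lineage in LINEAGES:
            counts = r.counts_md if lineage == LINEAGE_MD else r.counts_ad
            suffix = lineage.lower()
            rows.append(
                {
                    "bin_index": r.bin_index,
                    "p_upper": r.p_upper,
                    "p_lower": r.p_lower,
                    "lineage": lineage,
                    "a": counts.a,
                    "b": counts.b,
                    "c": counts.c,
                    "d": counts.d,
                    "f_score": getattr(r, f"f_score_{suffix}"),
                    "p_enrichment": r.p_enrichment,
                    "p_vs_background": getattr(r, f"p_enrichment_{suffix}_vs_background"),
                    "n_derived_risk": getattr(r, f"n_derived_risk_{suffix}"),
                    "n_derived_protective": getattr(r, f"n_derived_protective_{suffix}"),
                    "ratio": getattr(r, f"ratio_{suffix}"),
                    "p_ratio": r.p_ratio,
                }
            )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_bin_results(results, path) -> None:
    """Write one TSV row per (bin x lineage); undefined cells are ``NA``."""
    write_table(bin_results_frame(results), path)


def read_bin_results(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", na_values=["NA"], keep_default_na=False, float_precision="round_trip"
    )


def write_run_summary(summary: dict, path) -> None:
    """Write the machine-readable run summary (config echo, seed, counts)."""
    with Path(path).open("w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")


@dataclass
class PanelGenotypes:
    """Reference-panel genotype dosages keyed by (chrom, pos).

    Dosages are 0/1/2 counts of the ALT allele per sample, -1 for missing.
    The panel serves only as an LD reference: allele frequencies in the
    analysis come from the separate MAF table.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    dosages: np.ndarray  # (n_sites, n_samples) int8, -1 = missing
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._index:
            self._index = {
                (c, int(p)): i for i, (c, p) in enumerate(zip(self.chrom, self.pos))
            }

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[1]

    def __len__(self) -> int:
        return self.dosages.shape[0]

    def __contains__(self, key) -> bool:
        return key in self._index

    def row(self, chrom, pos) -> int:
        return self._index[(chrom, int(pos))]

    def get(self, chrom, pos) -> np.ndarray:
        return self.dosages[self.row(chrom, pos)]

    @classmethod
    def from_vcf(cls, path) -> "PanelGenotypes":
        """Load dosages from a VCF (plain or bgzipped) via cyvcf2."""
        from cyvcf2 import VCF

        # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        remap = np.array([0, 1, -1, 2], dtype=np.int8)
        chroms, positions, refs, alts, rows = [], [], [], [], []
        vcf = VCF(str(path))
        for variant in vcf:
            chroms.append(variant.CHROM)
            positions.append(variant.POS)
            refs.append(variant.REF)
            alts.append(variant.ALT[0] if variant.ALT else "N")
            rows.append(remap[variant.gt_types])
        vcf.close()
        return cls(
            chrom=np.array(chroms, dtype=object),
            pos=np.array(positions, dtype=np.int64),
            ref=np.array(refs, dtype=object),
            alt=np.array(alts, dtype=object),
            dosages=np.array(rows, dtype=np.int8)
            if rows
            else np.empty((0, 0), dtype=np.int8),
        )

    def to_vcf(self, path, sample_prefix: str = "S") -> None:
        """Write the panel as an unphased plain-text VCF 4.2."""
        gt_of = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
        n = self.n_samples
        with Path(path).open("w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            samples = "\t".join(f"{sample_prefix}{i}" for i in range(n))
            fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
            order = np.lexsort((self.pos, self.chrom.astype(str)))
            for i in order:
                gts = "\t".join(gt_of[int(d)] for d in self.dosages[i])
                fh.write(
                    f"{self.chrom[i]}\t{self.pos[i]}\t.\t{self.ref[i]}\t{self.alt[i]}"
                    f"\t.\tPASS\t.\tGT\t{gts}\n"
                )
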
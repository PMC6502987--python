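"""End-to-end orchestration: simulate/load -> prune -> annotate -> enrich.

The stage order follows the analytical design: LD pruning first (the
statistical tests assume independent SNPs), then site joining, MAF
attachment and filtering, polarity classification, then the binned
enrichment and ratio analyses. Batch mode applies the identical pipeline
to several GWAS datasets (the cross-disorder design). One global seed fans
out deterministically to per-dataset, per-stage child seeds, and every
filter's counts are logged into the machine-readable run summary.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as aio
from .annotate import attach_maf, classify_polarities
from .enrichment import EnrichmentAnalysis, EnrichmentResults
from .prune import prune
from .simulate import SimConfig, simulate, write_inputs
from .types import PruneConfig

logger = logging.getLogger(__name__)


@dataclass
class DatasetSpec:
    """One GWAS dataset for the (possibly batch) run.

    With ``gwas`` unset, inputs for the dataset are simulated from the run's
    base SimConfig merged with ``sim_overrides`` (e.g. a per-disorder
    protective_excess_md).
    """

    name: str = "dataset"
    gwas: str | None = None
    gwas_dialect: dict | None = None
    sim_overrides: dict = field(default_factory=dict)


@dataclass
class RunConfig:
    seed: int = 0
    datasets: list = field(default_factory=lambda: [DatasetSpec()])
    sim: SimConfig = field(default_factory=SimConfig)
    sites: str | None = None
    maf: str | None = None
    panel: str | None = None
    window_bp: int = 1_000_000
    r2_threshold: float = 0.2
    maf_threshold: float | None = 0.1
    maf_filter_scope: str = "both"
    n_bins: int = 10
    bin_mode: str = "empirical"
    edges: list | None = None
    fscore_convention: str = "printed"

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        sim_raw = dict(raw.pop("sim", {}))
        if "maf_beta_params" in sim_raw:
            sim_raw["maf_beta_params"] = tuple(sim_raw["maf_beta_params"])
        datasets = [
            DatasetSpec(**d) if isinstance(d, dict) else DatasetSpec(name=str(d))
            for d in raw.pop("datasets", [{}])
        ]
        return cls(sim=SimConfig(**sim_raw), datasets=datasets, **raw)

    def validate_paths(self) -> None:
        for p in (self.sites, self.maf, self.panel):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        for ds in self.datasets:
            if ds.gwas is not None and not Path(ds.gwas).exists():
                raise FileNotFoundError(ds.gwas)


@dataclass
class DatasetResult:
    name: str
    results: EnrichmentResults
    annotated: pd.DataFrame
    counts: dict


@dataclass
class RunBundle:
    config: RunConfig
    datasets: dict
    summary: dict


def _derive(root: np.random.SeedSequence, key) -> int:
    ss = np.random.SeedSequence(entropy=root.entropy, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def annotate_stage(gwas, sites, maf, retained_ids=None):
    """Join sites, attach MAF and classify polarity; returns (df, reports).

    When ``retained_ids`` (from pruning) is given, the GWAS set is first
    restricted to it.
    """
    if retained_ids is not None:
        gwas = gwas.loc[gwas["snp_id"].isin(set(retained_ids))].reset_index(drop=True)
    annotated, join_report = aio.join_sites(gwas, sites)
    annotated = attach_maf(annotated, maf)
    annotated = classify_polarities(annotated)
    return annotated, join_report


def _run_dataset(spec: DatasetSpec, config: RunConfig, outdir: Path, root: np.random.SeedSequence):
    ds_dir = outdir / spec.name
    ds_dir.mkdir(parents=True, exist_ok=True)
    counts: dict = {}

    if spec.gwas is None:
        sim_seed = _derive(root, (hash_name(spec.name), 0))
        sim_cfg = dataclasses.replace(config.sim, seed=sim_seed, **spec.sim_overrides)
        sim = simulate(sim_cfg)
        input_paths = write_inputs(sim, ds_dir / "inputs")
        counts["simulated"] = True
        counts["sim_seed"] = sim_seed
    else:
        input_paths = {
            "gwas": Path(spec.gwas),
            "sites": Path(config.sites),
            "maf": Path(config.maf),
            "panel": Path(config.panel),
        }
        counts["simulated"] = False

    gwas, gwas_report = aio.read_gwas(
        input_paths["gwas"], dialect=spec.gwas_dialect
    )
    sites, sites_report = aio.read_site_catalog(input_paths["sites"])
    maf, maf_report = aio.read_maf(input_paths["maf"])
    panel = aio.PanelGenotypes.from_vcf(input_paths["panel"])
    counts["read"] = {
        "gwas": gwas_report.as_dict(),
        "sites": sites_report.as_dict(),
        "maf": maf_report.as_dict(),
        "panel_sites": len(panel),
    }

    prune_seed = _derive(root, (hash_name(spec.name), 1))
    prune_result = prune(
        gwas, panel, PruneConfig(config.window_bp, config.r2_threshold, prune_seed)
    )
    counts["prune"] = {
        "n_pairs_flagged": prune_result.n_pairs_flagged,
        "n_removed": len(prune_result.removed),
        "n_retained": len(prune_result.retained),
        "n_untested": prune_result.n_untested,
        "seed": prune_result.seed,
    }
    (ds_dir / "retained_ids.txt").write_text(
        "\n".join(sorted(prune_result.retained)) + "\n"
    )

    annotated, join_report = annotate_stage(gwas, sites, maf, prune_result.retained)
    counts["join"] = join_report.as_dict()
    counts["excluded"] = (
        annotated["exclusion_reason"].value_counts().to_dict()
    )
    counts["polarity"] = annotated["polarity"].value_counts().to_dict()
    aio.write_table(annotated[aio.ANNOTATED_COLUMNS], ds_dir / "annotated.tsv")

    model = EnrichmentAnalysis(
        annotated,
        n_bins=config.n_bins,
        bin_mode=config.bin_mode,
        edges=config.edges,
        fscore_convention=config.fscore_convention,
        maf_threshold=config.maf_threshold,
        maf_filter_scope=config.maf_filter_scope,
    )
    results = model.fit()
    aio.write_bin_results(results.bin_results, ds_dir / "bin_results.tsv")

    counts["input_digests"] = {
        k: _digest(Path(p)) for k, p in sorted(input_paths.items())
    }
    counts["results"] = results.as_summary_dict()
    return DatasetResult(name=spec.name, results=results, annotated=annotated, counts=counts)


def hash_name(name: str) -> int:
    """Stable small integer from a dataset name (for seed derivation)."""
    return int.from_bytes(hashlib.blake2b(name.encode(), digest_size=4).digest(), "little")


def run_pipeline(config: RunConfig, outdir) -> RunBundle:
    """Run the full pipeline for every dataset; write tables and summary.

    Identical config and seed produce byte-identical outputs.
    """
    config.validate_paths()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    datasets = {}
    for spec in config.datasets:
        logger.info("running dataset %s", spec.name)
        datasets[spec.name] = _run_dataset(spec, config, outdir, root)

    summary = {
        "seed": config.seed,
        "config": _config_echo(config),
        "datasets": {name: ds.counts for name, ds in sorted(datasets.items())},
    }
    aio.write_run_summary(summary, outdir / "run_summary.json")
    bundle = RunBundle(config=config, datasets=datasets, summary=summary)
    (outdir / "report.txt").write_text(report(bundle))
    return bundle


def _config_echo(config: RunConfig) -> dict:
    echo = dataclasses.asdict(config)
    echo["sim"]["maf_beta_params"] = list(echo["sim"]["maf_beta_params"])
    return echo


def report(bundle: RunBundle) -> str:
    """Human-readable multi-dataset report of the fitted results."""
    lines = [
        "archaicsel run report",
        f"seed: {bundle.config.seed}   "
        f"prune: window {bundle.config.window_bp} bp, r2 > {bundle.config.r2_threshold}   "
        f"MAF < {bundle.config.maf_threshold} ({bundle.config.maf_filter_scope})",
        "",
    ]
    for name in sorted(bundle.datasets):
        ds = bundle.datasets[name]
        lines.append(f"### dataset: {name}")
        lines.append(ds.results.summary())
        lines.append("")
    return "\n".join(lines)
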
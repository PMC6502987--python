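import numpy as np
import pytest

from archaicsel import PanelGenotypes, SimConfig, simulate
from archaicsel.pipeline import annotate_stage

SMALL_SIM = SimConfig(
    n_snps=3000,
    n_md_sites=600,
    n_ad_sites=450,
    n_ld_blocks=750,
    seed=11,
)


@pytest.fixture(scope="session")
def small_sim():
    """One small synthetic dataset shared across read-only tests."""
    return simulate(SMALL_SIM)


@pytest.fixture(scope="session")
def small_annotated(small_sim):
    """Annotated SNP table for the small dataset (no pruning)."""
    annotated, _ = annotate_stage(small_sim.gwas, small_sim.sites, small_sim.maf)
    return annotated


def make_panel(positions, dosage_rows, chrom="1"):
    """Hand-built reference panel for pruning unit tests."""
    n = len(positions)
    return PanelGenotypes(
        chrom=np.array([chrom] * n, dtype=object),
        pos=np.array(positions, dtype=np.int64),
        ref=np.array(["A"] * n, dtype=object),
        alt=np.array(["G"] * n, dtype=object),
        dosages=np.array(dosage_rows, dtype=np.int8),
    )
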
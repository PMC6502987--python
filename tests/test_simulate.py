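import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from archaicsel import (
    SimConfig,
    read_gwas,
    read_maf,
    read_site_catalog,
    simulate,
    simulate_panel,
    simulate_resolved_polarities,
    write_inputs,
)


def test_same_seed_same_dataset(tmp_path):
    cfg = SimConfig(n_snps=500, n_md_sites=100, n_ad_sites=80, n_ld_blocks=125, seed=9)
    a, b = simulate(cfg), simulate(cfg)
    pd.testing.assert_frame_equal(a.gwas, b.gwas)
    pd.testing.assert_frame_equal(a.sites, b.sites)
    np.testing.assert_array_equal(a.panel.dosages, b.panel.dosages)
    # and byte-identical files
    pa = write_inputs(a, tmp_path / "a")
    pb = write_inputs(b, tmp_path / "b")
    for key in pa:
        assert pa[key].read_bytes() == pb[key].read_bytes()


def test_perfect_ld_blocks_are_identical_vectors():
    cfg = SimConfig(n_snps=40, n_md_sites=5, n_ad_sites=5, n_ld_blocks=8, within_block_r2=1.0, seed=2)
    panel, block = simulate_panel(cfg)
    for b in range(8):
        rows = panel.dosages[block == b]
        assert (rows == rows[0]).all()


def test_cross_block_r2_matches_null_expectation():
    """Independent sites: mean squared sample correlation ~ 1/(n_samples-1).

    With within_block_r2 = 0 every site is an independent draw, giving
    ~20,000 pairs for the Monte-Carlo check of the null expectation of r^2.
    """
    cfg = SimConfig(
        n_snps=200, n_md_sites=5, n_ad_sites=5, n_ld_blocks=2,
        n_samples_panel=100, within_block_r2=0.0, block_spacing_bp=10_000_000, seed=4,
    )
    panel, _ = simulate_panel(cfg)
    d = panel.dosages.astype(float)
    z = (d - d.mean(1, keepdims=True)) / d.std(1, keepdims=True)
    r2 = (z @ z.T / d.shape[1]) ** 2
    off = r2[~np.eye(len(r2), dtype=bool)]
    assert off.mean() == pytest.approx(1 / 99, rel=0.25)


def test_cross_block_independent_of_within_block_ld():
    cfg = SimConfig(
        n_snps=200, n_md_sites=5, n_ad_sites=5, n_ld_blocks=2,
        n_samples_panel=100, within_block_r2=0.9, block_spacing_bp=10_000_000, seed=4,
    )
    panel, block = simulate_panel(cfg)
    d = panel.dosages.astype(float)
    z = (d - d.mean(1, keepdims=True)) / d.std(1, keepdims=True)
    r2 = (z @ z.T / d.shape[1]) ** 2
    cross = r2[np.ix_(block == 0, block == 1)]
    within = r2[np.ix_(block == 0, block == 0)]
    off = within[~np.eye(len(within), dtype=bool)]
    assert 0.75 < off.mean() < 1.0
    assert cross.mean() < 0.05  # uncorrelated across blocks


def test_null_theta_counts_are_balanced(small_sim):
    for lin, c in small_sim.truth.counts.items():
        n = c["risk"] + c["protective"]
        # binomial(n, 1/2) 99.9% interval
        halfwidth = 3.3 * np.sqrt(n * 0.25)
        assert abs(c["risk"] - n / 2) < halfwidth


def test_injected_protective_excess_recovered():
    cfg = SimConfig(
        n_snps=6000, n_md_sites=5000, n_ad_sites=1000, overlap_fraction=1.0,
        n_ld_blocks=1500, protective_excess_md=2.0, seed=21,
    )
    sim = simulate(cfg)
    c = sim.truth.counts["MD"]
    n = c["risk"] + c["protective"]
    assert n == 5000
    share = c["protective"] / n
    assert abs(share - 2 / 3) < 1.96 * np.sqrt((2 / 9) / n)  # binomial 95% CI


def test_realized_theta_converges_at_large_n():
    cfg = SimConfig(
        n_snps=50_000, n_md_sites=49_000, n_ad_sites=1_000, overlap_fraction=1.0,
        n_ld_blocks=5000, protective_excess_md=2.0, seed=8,
    )
    sim = simulate(cfg)
    assert sim.truth.realized_theta["MD"] == pytest.approx(2.0, rel=0.02)


def test_null_p_values_uniform():
    cfg = SimConfig(
        n_snps=5000, n_md_sites=500, n_ad_sites=400, n_ld_blocks=1250,
        assoc_effect_fraction=0.0, seed=13,
    )
    sim = simulate(cfg)
    assert kstest(sim.gwas["p_value"], "uniform").pvalue > 0.01


def test_site_snp_maf_capped_below_filter(small_sim):
    site_pos = set(
        small_sim.sites.loc[small_sim.sites["pos"].isin(small_sim.gwas["pos"]), "pos"]
    )
    maf = small_sim.maf.set_index("snp_id")["maf"]
    site_ids = small_sim.gwas.loc[small_sim.gwas["pos"].isin(site_pos), "snp_id"]
    assert (maf.loc[site_ids] < 0.1).all()
    assert (small_sim.maf["maf"] > 0).all() and (small_sim.maf["maf"] <= 0.5).all()


def test_site_maf_cap_can_be_disabled():
    cfg = SimConfig(
        n_snps=2000, n_md_sites=1000, n_ad_sites=500, overlap_fraction=1.0,
        n_ld_blocks=500, cap_site_maf=False, seed=3,
    )
    sim = simulate(cfg)
    assert (sim.maf["maf"] >= 0.1).any()


def test_generated_files_reread_with_zero_rejects(tmp_path, small_sim):
    paths = write_inputs(small_sim, tmp_path)
    for reader, key in [(read_gwas, "gwas"), (read_site_catalog, "sites"), (read_maf, "maf")]:
        _, report = reader(paths[key])
        assert report.n_rejected == 0
        assert report.n_accepted == report.n_rows


def test_config_validation():
    with pytest.raises(ValueError):
        SimConfig(n_samples_panel=3)
    with pytest.raises(ValueError):
        SimConfig(protective_excess_md=0.5)
    with pytest.raises(ValueError):
        SimConfig(overlap_fraction=0.0)
    with pytest.raises(ValueError):
        simulate(SimConfig(n_snps=100, n_md_sites=200, n_ad_sites=200, overlap_fraction=1.0, n_ld_blocks=10))


def test_resolved_polarity_shortcut_matches_theta():
    rng = np.random.default_rng(5)
    df = simulate_resolved_polarities(20_000, 1_000, theta_md=3.0, rng=rng)
    md = df[df["lineage"] == "MD"]
    share = (md["polarity"] == "derived_protective").mean()
    assert share == pytest.approx(0.75, abs=0.01)
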
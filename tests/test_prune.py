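import numpy as np
import pandas as pd
import pytest

from archaicsel import PruneConfig, SimConfig, compute_r2, prune, simulate
from conftest import make_panel


def _snps(positions, chrom="1"):
    return pd.DataFrame(
        {
            "snp_id": [f"s{i}" for i in range(len(positions))],
            "chrom": [chrom] * len(positions),
            "pos": positions,
        }
    )


def test_compute_r2_identity():
    assert compute_r2([0, 1, 2, 0, 1], [0, 1, 2, 0, 1]) == pytest.approx(1.0)


def test_compute_r2_hand_pearson():
    # cov 0.3125, both variances 0.6875 -> r = 0.4545..., r^2 = 0.2066...
    assert compute_r2([0, 1, 2, 0], [0, 1, 2, 2]) == pytest.approx(0.3125**2 / 0.6875**2)


def test_compute_r2_undefined_cases():
    assert compute_r2([0, 0, 0, 0], [0, 1, 2, 1]) is None  # constant
    assert compute_r2([0, 1, -1, -1], [0, 1, 2, 1]) is None  # < 4 complete
    assert compute_r2([0, 1, 2, -1, 0], [0, 1, 2, 1, -1]) is None


def test_compute_r2_pairwise_complete():
    # missing entries removed pairwise; remaining vectors identical
    assert compute_r2([0, 1, 2, 0, -1], [0, 1, 2, 0, 2]) == pytest.approx(1.0)


VEC = [0, 1, 2, 0, 1, 2, 0, 2]


def test_correlated_pair_within_window_prunes_one():
    panel = make_panel([100, 500_100], [VEC, VEC])
    outcomes = set()
    for seed in range(20):
        result = prune(_snps([100, 500_100]), panel, PruneConfig(seed=seed))
        assert len(result.retained) == 1 and len(result.removed) == 1
        assert result.n_pairs_flagged == 1
        # fixed per seed
        again = prune(_snps([100, 500_100]), panel, PruneConfig(seed=seed))
        assert again.retained == result.retained
        outcomes.add(next(iter(result.retained)))
    assert outcomes == {"s0", "s1"}  # both branches exercised across seeds


def test_pair_outside_window_kept():
    panel = make_panel([100, 1_500_100], [VEC, VEC])
    result = prune(_snps([100, 1_500_100]), panel, PruneConfig())
    assert len(result.retained) == 2 and result.n_pairs_flagged == 0


def test_triple_mutually_correlated_keeps_exactly_one():
    panel = make_panel([100, 200, 300], [VEC, VEC, VEC])
    for seed in range(8):
        result = prune(_snps([100, 200, 300]), panel, PruneConfig(seed=seed))
        assert len(result.retained) == 1


def test_snp_missing_from_panel_passes_untested():
    panel = make_panel([100], [VEC])
    result = prune(_snps([100, 999]), panel, PruneConfig())
    assert result.retained == {"s0", "s1"}
    assert result.n_untested == 1


def test_constant_dosage_pair_unflagged():
    panel = make_panel([100, 200], [VEC, [1] * 8])
    result = prune(_snps([100, 200]), panel, PruneConfig())
    assert len(result.retained) == 2 and result.n_pairs_flagged == 0


def test_empty_input():
    panel = make_panel([100], [VEC])
    result = prune(_snps([]), panel, PruneConfig())
    assert result.retained == frozenset() and result.removed == frozenset()


@pytest.fixture(scope="module")
def block_sim():
    return simulate(
        SimConfig(n_snps=1000, n_md_sites=200, n_ad_sites=150, n_ld_blocks=250, seed=5)
    )


def _r2_matrix(panel):
    d = panel.dosages.astype(float)
    sd = d.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (d - d.mean(axis=1, keepdims=True)) / sd
    r = z @ z.T / d.shape[1]
    return r * r


def test_no_retained_pair_exceeds_threshold(block_sim):
    """Brute-force all-pairs verification of the pruning post-condition."""
    config = PruneConfig(seed=7)
    result = prune(block_sim.gwas, block_sim.panel, config)
    kept = block_sim.gwas.loc[block_sim.gwas["snp_id"].isin(result.retained)]
    rows = [block_sim.panel.row(c, p) for c, p in zip(kept["chrom"], kept["pos"])]
    r2 = _r2_matrix(block_sim.panel)[np.ix_(rows, rows)]
    pos = kept["pos"].to_numpy()
    close = np.abs(pos[:, None] - pos[None, :]) <= config.window_bp
    np.fill_diagonal(close, False)
    sd = block_sim.panel.dosages[rows].astype(float).std(axis=1)
    nonconst = (sd > 0)[:, None] & (sd > 0)[None, :]
    assert not (close & nonconst & (r2 > config.r2_threshold)).any()
    assert result.retained | result.removed == set(block_sim.gwas["snp_id"])
    assert not (result.retained & result.removed)


def test_prune_idempotent(block_sim):
    config = PruneConfig(seed=7)
    first = prune(block_sim.gwas, block_sim.panel, config)
    subset = block_sim.gwas.loc[block_sim.gwas["snp_id"].isin(first.retained)]
    second = prune(subset, block_sim.panel, config)
    assert second.retained == first.retained
    assert second.n_pairs_flagged == 0


def test_prune_deterministic_per_seed(block_sim):
    a = prune(block_sim.gwas, block_sim.panel, PruneConfig(seed=3))
    b = prune(block_sim.gwas, block_sim.panel, PruneConfig(seed=3))
    assert a == b


def test_raising_threshold_never_shrinks_retained_count(block_sim):
    for seed in (0, 1):
        sizes = [
            len(prune(block_sim.gwas, block_sim.panel, PruneConfig(r2_threshold=t, seed=seed)).retained)
            for t in (0.05, 0.2, 0.5, 0.8, 0.95)
        ]
        assert sizes == sorted(sizes)
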
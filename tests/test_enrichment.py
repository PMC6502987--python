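import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from archaicsel import (
    EnrichmentAnalysis,
    simulate_resolved_polarities,
)
from archaicsel.enrichment import enrichment_by_bin, overall_contrast, ratio_by_bin
from archaicsel.stats import make_bins


def _universe(p_values, lineage):
    return pd.DataFrame({"p_value": p_values, "lineage": lineage})


def test_conservation_of_bin_counts(small_annotated):
    results = EnrichmentAnalysis(small_annotated).fit()
    for suffix in ("md", "ad"):
        counts = [getattr(r, f"counts_{suffix}") for r in results.bin_results]
        assert sum(cc.d for cc in counts) == counts[0].b
        assert sum(cc.c for cc in counts) == counts[0].a
    assert sum(cc.c for cc in counts) == results.n_analyzed


def test_every_analyzed_snp_in_exactly_one_bin(small_annotated):
    results = EnrichmentAnalysis(small_annotated).fit()
    universe = small_annotated.loc[
        small_annotated["exclusion_reason"].isna() & (small_annotated["maf"] < 0.1)
    ]
    bins = results.partition.assign(universe["p_value"].to_numpy())
    assert len(bins) == results.n_analyzed
    assert np.bincount(bins, minlength=10).sum() == results.n_analyzed


def test_point_mass_limit():
    """All MD-site SNPs forced into the lowest-p bin."""
    rng = np.random.default_rng(0)
    n, n_md = 1000, 50
    p = np.concatenate([rng.uniform(0.1, 1.0, n - n_md), rng.uniform(0, 0.05, n_md)])
    lineage = np.array([None] * (n - n_md) + ["MD"] * n_md, dtype=object)
    part = make_bins(None, mode="fixed", edges=np.linspace(0, 1, 11))
    results = enrichment_by_bin(_universe(p, lineage), part, convention="obs_exp")
    bottom = results[-1]
    assert bottom.counts_md.d == n_md
    # d = b in the bottom bin, so observed/expected F = a / c there, 0 elsewhere
    assert bottom.f_score_md == pytest.approx(bottom.counts_md.a / bottom.counts_md.c)
    for r in results[:-1]:
        assert r.f_score_md == 0.0


def test_ratio_by_bin_worked_example():
    # one bin: MD 10 risk / 20 protective, AD 20 risk / 10 protective
    rows = (
        [("MD", "derived_risk")] * 10
        + [("MD", "derived_protective")] * 20
        + [("AD", "derived_risk")] * 20
        + [("AD", "derived_protective")] * 10
    )
    df = pd.DataFrame(rows, columns=["lineage", "polarity"])
    df["p_value"] = 0.5
    part = make_bins(None, mode="fixed", edges=[0.0, 1.0])
    (r,) = ratio_by_bin(df, part)
    assert r.ratio_md == pytest.approx(0.5)
    assert r.ratio_ad == pytest.approx(2.0)
    assert r.p_ratio == pytest.approx(0.019383188261789967, abs=1e-12)


def test_identical_counts_give_p_one():
    rows = [("MD", "derived_risk")] * 5 + [("MD", "derived_protective")] * 7
    rows += [("AD", "derived_risk")] * 5 + [("AD", "derived_protective")] * 7
    df = pd.DataFrame(rows, columns=["lineage", "polarity"])
    df["p_value"] = 0.3
    part = make_bins(None, mode="fixed", edges=[0.0, 1.0])
    (r,) = ratio_by_bin(df, part)
    assert r.p_ratio == 1.0
    assert r.ratio_md == r.ratio_ad
    assert overall_contrast([r], "ratio").p_value == 1.0


def test_empty_bin_is_na():
    df = _universe([0.95] * 20, [None] * 20)
    part = make_bins(None, mode="fixed", edges=np.linspace(0, 1, 11))
    results = enrichment_by_bin(df, part)
    empty = results[5]
    assert empty.counts_md.c == 0
    assert math.isnan(empty.f_score_md) and math.isnan(empty.p_enrichment)


def test_enrichment_null_is_calibrated():
    """Equal-rate site classes scattered uniformly over p: F-scores center
    on 1 and the per-bin MD-vs-AD test holds its nominal size, so a
    replicate with any bin below 0.005 occurs at most at the
    1 - (1 - 0.005)^10 ~ 5% rate the ten bins imply."""
    rng = np.random.default_rng(99)
    n = 4000
    n_extreme = 0
    n_reject = 0
    f_scores = []
    reps = 200
    for _ in range(reps):
        p = rng.uniform(size=n)
        lineage = rng.choice([None, "MD", "AD"], size=n, p=[0.8, 0.1, 0.1])
        part = make_bins(p)
        results = enrichment_by_bin(_universe(p, lineage), part)
        f_scores.extend(r.f_score_md for r in results)
        n_reject += sum(r.p_enrichment < 0.005 for r in results)
        if min(r.p_enrichment for r in results) < 0.005:
            n_extreme += 1
    assert np.nanmean(f_scores) == pytest.approx(1.0, abs=0.05)
    assert n_reject / (10 * reps) < 0.01  # nominal 0.005, MC slack
    assert n_extreme <= 20  # binomial 99.9% bound at the implied 4.9% rate


def test_pooled_null_p_uniform():
    rng = np.random.default_rng(7)
    ps = []
    for _ in range(300):
        df = simulate_resolved_polarities(1000, 1000, rng=rng)
        part = make_bins(df["p_value"].to_numpy())
        ps.append(overall_contrast(ratio_by_bin(df, part), "ratio").p_value)
    assert kstest(ps, "uniform").pvalue > 0.01


def test_fixed_paper_edges_through_model(small_annotated):
    from archaicsel.stats import PAPER_DECILE_EDGES

    results = EnrichmentAnalysis(
        small_annotated, bin_mode="fixed", edges=PAPER_DECILE_EDGES
    ).fit()
    assert results.bin_results[0].p_upper == 1.0
    assert results.bin_results[0].p_lower == 0.886
    assert results.bin_results[9].p_lower == 0.0


def test_maf_filter_scope_switch(small_annotated):
    both = EnrichmentAnalysis(small_annotated, maf_filter_scope="both").fit()
    enr_only = EnrichmentAnalysis(small_annotated, maf_filter_scope="enrichment_only").fit()
    # site SNP MAFs are capped below 0.1 in the generator, so the resolved
    # set only grows when the filter is lifted from the ratio analysis
    for lin in ("MD", "AD"):
        assert enr_only.n_resolved[lin] >= both.n_resolved[lin]
    assert enr_only.n_analyzed == both.n_analyzed


def test_results_surface(small_annotated):
    results = EnrichmentAnalysis(small_annotated).fit()
    frame = results.to_frame()
    assert frame.shape[0] == 20
    text = results.summary()
    assert "F-score convention: printed" in text
    assert "overall MD-vs-AD" in text
    d = results.as_summary_dict()
    assert 0 <= d["overall_ratio_p"] <= 1
    assert len(d["bin_edges"]) == 11
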
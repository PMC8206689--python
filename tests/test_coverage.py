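"""Coverage-ratio scan: masking, windowing, standardization, classification."""

import numpy as np
import pandas as pd
import pytest

from sexscan.coverage import (CALL_AMBIGUOUS, CALL_AUTOSOMAL, CALL_X_LINKED,
                              CALL_Z_LINKED, DepthTrack, coverage_pipeline,
                              filter_low_female, mask_high_coverage,
                              region_report, standardize_and_ratio,
                              summarize_and_classify, window_means)
from sexscan.genome import GenomeModel

from _oracles import naive_window_table


def constant_track(genome, value, sex="F", overrides=None):
    """Track with constant depth, optionally overriding whole chromosomes
    or (chrom, start, end, value) patches (1-based closed)."""
    depth = {c: np.full(ln, value, dtype=np.int64)
             for c, ln in genome.chromosomes}
    for patch in overrides or []:
        chrom, start, end, v = patch
        depth[chrom][start - 1:end] = v
    return DepthTrack(genome=genome, depth=depth, sex=sex, sample=sex)


# ---------------------------------------------------------------- masking

def test_mask_cap_is_strictly_greater_than():
    g = GenomeModel((("c", 3),))
    t = DepthTrack(genome=g, depth={"c": np.array([100, 200, 201])})
    masked = mask_high_coverage(t, cap=200)
    assert list(masked.mask["c"]) == [False, False, True]
    # depths untouched
    assert list(masked.depth["c"]) == [100, 200, 201]


def test_mask_identity_and_zero_cap():
    g = GenomeModel((("c", 4),))
    t = DepthTrack(genome=g, depth={"c": np.array([0, 5, 10, 200])})
    assert not mask_high_coverage(t, cap=200).mask["c"].any()
    zero = mask_high_coverage(t, cap=0)
    assert list(zero.mask["c"]) == [False, True, True, True]


# ---------------------------------------------------------------- windows

def test_window_means_constant_and_partial(tiny_genome):
    t = constant_track(tiny_genome, 25)
    wm = window_means(t, 5)
    df = wm.windows
    a = df[df["chrom"] == "chrA"]
    assert len(a) == 2 and (a["mean"] == 25).all() and not a["partial"].any()
    # chrB is 12 bp: third window covers 11-12 and is partial
    b = df[df["chrom"] == "chrB"]
    assert list(b["start"]) == [1, 6, 11]
    assert list(b["end"]) == [5, 10, 12]
    assert list(b["partial"]) == [False, False, True]


def test_window_mean_ignores_masked_positions():
    g = GenomeModel((("c", 4),))
    t = DepthTrack(genome=g, depth={"c": np.array([10, 10, 30, 999])},
                   mask={"c": np.array([False, False, False, True])})
    wm = window_means(t, 4)
    assert wm.windows["mean"].iloc[0] == pytest.approx(50 / 3, rel=1e-15)


def test_fully_masked_window_is_missing():
    g = GenomeModel((("c", 8),))
    t = DepthTrack(genome=g, depth={"c": np.array([5] * 8)},
                   mask={"c": np.array([True] * 4 + [False] * 4)})
    means = window_means(t, 4).windows["mean"]
    assert np.isnan(means.iloc[0]) and means.iloc[1] == 5


def test_terminal_window_tiling_12kb_chromosome():
    g = GenomeModel((("c", 12_000),))
    t = constant_track(g, 10)
    df = window_means(t, 5_000).windows
    assert list(df["start"]) == [1, 5_001, 10_001]
    assert list(df["end"]) == [5_000, 10_000, 12_000]
    assert list(df["partial"]) == [False, False, True]


# ------------------------------------------------------- standardization

def test_identical_tracks_give_ratio_exactly_one(small_genome):
    f = constant_track(small_genome, 25, "F")
    m = constant_track(small_genome, 25, "M")
    table = standardize_and_ratio(window_means(f, 5000), window_means(m, 5000))
    assert (table.df["ratio"] == 1.0).all()


def test_x0_closed_form_ratios():
    # constant female depth d; male depth d except d/2 on chr1 of 10 equal
    # chromosomes: male genome mean 0.95 d, so autosomal R = 0.95 and the
    # hemizygous chromosome lands at 1.9 (not 2.0)
    g = GenomeModel.default(n_chromosomes=10, length=10_000)
    d = 40
    f = constant_track(g, d, "F")
    m = constant_track(g, d, "M", overrides=[("chr1", 1, 10_000, d // 2)])
    table = standardize_and_ratio(window_means(f, 5000), window_means(m, 5000))
    assert table.cbar_m == pytest.approx(0.95 * d, rel=1e-14)
    hemi = table.df[table.df["chrom"] == "chr1"]["ratio"]
    auto = table.df[table.df["chrom"] != "chr1"]["ratio"]
    assert hemi.to_numpy() == pytest.approx(1.9, rel=1e-12)
    assert auto.to_numpy() == pytest.approx(0.95, rel=1e-12)


def test_zw_mirror_closed_form_ratios():
    g = GenomeModel.default(n_chromosomes=10, length=10_000)
    d = 40
    f = constant_track(g, d, "F", overrides=[("chr1", 1, 10_000, d // 2)])
    m = constant_track(g, d, "M")
    table = standardize_and_ratio(window_means(f, 5000), window_means(m, 5000))
    z = table.df[table.df["chrom"] == "chr1"]["ratio"]
    auto = table.df[table.df["chrom"] != "chr1"]["ratio"]
    assert z.to_numpy() == pytest.approx(0.5 / 0.95, rel=1e-12)
    assert auto.to_numpy() == pytest.approx(1 / 0.95, rel=1e-12)


def test_degenerate_all_zero_coverage_errors(tiny_genome):
    f = constant_track(tiny_genome, 0, "F")
    m = constant_track(tiny_genome, 25, "M")
    with pytest.raises(ValueError, match="zero|degenerate"):
        standardize_and_ratio(window_means(f, 5), window_means(m, 5))


def test_normalization_identity_exact(small_genome):
    # depth-weighted mean of z over unmasked positions is exactly 1
    rng = np.random.default_rng(5)
    depth = {c: rng.poisson(25, ln).astype(np.int64)
             for c, ln in small_genome.chromosomes}
    t = DepthTrack(genome=small_genome, depth=depth, sex="F")
    t = mask_high_coverage(t, 40)
    cbar = t.unmasked_mean()
    z_sum = sum((t.depth[c][~t.mask[c]] / cbar).sum()
                for c in small_genome.names)
    n = sum((~t.mask[c]).sum() for c in small_genome.names)
    assert z_sum / n == pytest.approx(1.0, abs=1e-12)


def test_swapping_sexes_inverts_every_finite_ratio(small_genome):
    rng = np.random.default_rng(11)
    mk = lambda sex: DepthTrack(
        genome=small_genome, sex=sex,
        depth={c: rng.poisson(20, ln).astype(np.int64)
               for c, ln in small_genome.chromosomes})
    f, m = mk("F"), mk("M")
    fw, mw = window_means(f, 5000), window_means(m, 5000)
    r_fm = standardize_and_ratio(fw, mw).df["ratio"]
    r_mf = standardize_and_ratio(mw, fw).df["ratio"]
    finite = np.isfinite(r_fm) & np.isfinite(r_mf)
    assert np.allclose(r_fm[finite] * r_mf[finite], 1.0, rtol=1e-12)


def test_scaling_one_sex_leaves_ratios_unchanged(small_genome):
    rng = np.random.default_rng(12)
    depth = {c: rng.poisson(20, ln).astype(np.int64)
             for c, ln in small_genome.chromosomes}
    f = DepthTrack(genome=small_genome, depth=depth, sex="F")
    m = DepthTrack(genome=small_genome, sex="M",
                   depth={c: rng.poisson(20, ln).astype(np.int64)
                          for c, ln in small_genome.chromosomes})
    base = standardize_and_ratio(window_means(f, 5000), window_means(m, 5000))
    f7 = DepthTrack(genome=small_genome, sex="F",
                    depth={c: depth[c] * 7 for c in depth})
    scaled = standardize_and_ratio(window_means(f7, 5000),
                                   window_means(m, 5000))
    assert np.allclose(base.df["ratio"], scaled.df["ratio"],
                       rtol=1e-12, equal_nan=True)


def test_window_table_matches_naive_per_position_oracle():
    g = GenomeModel((("c", 10_000),))
    rng = np.random.default_rng(3)
    df_depth = rng.poisson(25, 10_000).astype(np.int64)
    dm_depth = rng.poisson(25, 10_000).astype(np.int64)
    df_depth[rng.choice(10_000, 50, replace=False)] = 500  # force masking
    f = mask_high_coverage(DepthTrack(genome=g, depth={"c": df_depth},
                                      sex="F"), 200)
    m = mask_high_coverage(DepthTrack(genome=g, depth={"c": dm_depth},
                                      sex="M"), 200)
    table = standardize_and_ratio(window_means(f, 1000), window_means(m, 1000))
    oracle = naive_window_table(df_depth, dm_depth, f.mask["c"], m.mask["c"],
                                1000)
    for got, want in zip(table.df.itertuples(), oracle):
        for col in ("c_F", "c_M", "z_F", "z_M", "ratio"):
            assert getattr(got, col) == pytest.approx(want[col], rel=1e-12)


# ------------------------------------------------------------- filtering

def test_low_female_filter_is_strict_below_five(small_genome):
    f = constant_track(small_genome, 25, "F",
                       overrides=[("chr1", 1, 5000, 4),  # mean 4 -> flagged
                                  ("chr2", 1, 5000, 5)])  # mean 5 -> kept
    m = constant_track(small_genome, 25, "M")
    table = standardize_and_ratio(window_means(f, 5000),
                                  window_means(m, 5000))
    table = filter_low_female(table, 5.0)
    w1 = table.df[(table.df["chrom"] == "chr1") & (table.df["start"] == 1)]
    w2 = table.df[(table.df["chrom"] == "chr2") & (table.df["start"] == 1)]
    assert bool(w1["low_female"].iloc[0]) and np.isnan(w1["ratio"].iloc[0])
    assert not bool(w2["low_female"].iloc[0])
    assert np.isfinite(w2["ratio"].iloc[0])


def test_male_zero_window_kept_and_flagged(small_genome):
    f = constant_track(small_genome, 25, "F")
    m = constant_track(small_genome, 25, "M",
                       overrides=[("chr3", 1, 5000, 0)])
    table = filter_low_female(standardize_and_ratio(
        window_means(f, 5000), window_means(m, 5000)))
    w = table.df[(table.df["chrom"] == "chr3") & (table.df["start"] == 1)]
    assert bool(w["male_zero"].iloc[0])
    assert not bool(w["low_female"].iloc[0])
    assert np.isnan(w["ratio"].iloc[0])
    runs = summarize_and_classify(table).male_zero_runs
    assert len(runs) == 1 and runs["chrom"].iloc[0] == "chr3"


# ---------------------------------------------------------- classification

def test_constant_ratio_one_classifies_all_autosomal(small_genome):
    f = constant_track(small_genome, 25, "F")
    m = constant_track(small_genome, 25, "M")
    _, summary = coverage_pipeline(f, m, 5000)
    assert (summary.per_chromosome["call"] == CALL_AUTOSOMAL).all()
    assert summary.genome_mean == pytest.approx(1.0)
    assert summary.genome_sd == 0.0
    assert len(summary.outliers) == 0


def test_x0_construction_classified_x_linked():
    g = GenomeModel.default(n_chromosomes=10, length=10_000)
    f = constant_track(g, 40, "F")
    m = constant_track(g, 40, "M", overrides=[("chr1", 1, 10_000, 20)])
    _, summary = coverage_pipeline(f, m, 1000)
    calls = dict(zip(summary.per_chromosome["chrom"],
                     summary.per_chromosome["call"]))
    assert calls["chr1"] == CALL_X_LINKED
    assert all(c == CALL_AUTOSOMAL for k, c in calls.items() if k != "chr1")


def test_zw_construction_classified_z_linked():
    g = GenomeModel.default(n_chromosomes=10, length=10_000)
    f = constant_track(g, 40, "F", overrides=[("chr4", 1, 10_000, 20)])
    m = constant_track(g, 40, "M")
    _, summary = coverage_pipeline(f, m, 1000)
    calls = dict(zip(summary.per_chromosome["chrom"],
                     summary.per_chromosome["call"]))
    assert calls["chr4"] == CALL_Z_LINKED


def test_single_outlier_region_does_not_flip_chromosome_call():
    g = GenomeModel.default(n_chromosomes=10, length=100_000)
    f = constant_track(g, 40, "F")
    # one 10 kb region at doubled ratio inside chr2
    m = constant_track(g, 40, "M", overrides=[("chr2", 20_001, 30_000, 20)])
    table, summary = coverage_pipeline(f, m, 10_000)
    calls = dict(zip(summary.per_chromosome["chrom"],
                     summary.per_chromosome["call"]))
    assert calls["chr2"] == CALL_AUTOSOMAL
    out = summary.outliers
    assert len(out) == 1
    assert out.iloc[0]["chrom"] == "chr2" and out.iloc[0]["start"] == 20_001


def test_chromosome_without_usable_windows_is_ambiguous():
    g = GenomeModel((("c1", 1000), ("c2", 1000)))
    f = constant_track(g, 25, "F", overrides=[("c2", 1, 1000, 1)])  # low F
    m = constant_track(g, 25, "M")
    table, _ = coverage_pipeline(f, m, 1000)
    with pytest.warns(UserWarning, match="c2"):
        summary = summarize_and_classify(table)
    calls = dict(zip(summary.per_chromosome["chrom"],
                     summary.per_chromosome["call"]))
    assert calls["c2"] == CALL_AMBIGUOUS


# ---------------------------------------------------------- region report

def test_region_report_overlap_semantics(small_genome):
    f = constant_track(small_genome, 25, "F")
    m = constant_track(small_genome, 25, "M")
    table, _ = coverage_pipeline(f, m, 5000)
    one = region_report(table, "chr1", 5001, 10_000)
    assert len(one) == 1 and one["start"].iloc[0] == 5001
    spanning = region_report(table, "chr1", 2500, 13_000)  # 2.5 windows
    assert len(spanning) == 3
    with pytest.raises(ValueError, match="outside|unknown"):
        region_report(table, "chr1", 1, 10_000_000)


def test_region_report_on_autosomal_simulation_within_band(small_genome):
    from sexscan.simulate import ScenarioSpec, SimConfig, simulate_depth
    cfg = SimConfig(seed=42)
    f = simulate_depth(small_genome, ScenarioSpec(), cfg, "F")
    m = simulate_depth(small_genome, ScenarioSpec(), cfg, "M")
    table, _ = coverage_pipeline(f, m, 5000)
    rows = region_report(table, "chr5", 10_001, 30_000)
    assert (rows["ratio"].between(0.8, 1.2)).all()
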
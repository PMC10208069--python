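import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bulkmap as bm
from bulkmap.bsa import (FILTER_RULES, PoolCounts, annotate_significance,
                         call_peaks, delta_snp_index, ed2, filter_variants,
                         null_thresholds, quantile_thresholds,
                         site_statistics, sliding_windows, snp_index,
                         window_site_depths)
from bulkmap.errors import BulkmapError, UndefinedValueError
from bulkmap.variant_io import SampleCall, SampleRoles, VariantRecord

ROLES = SampleRoles()


def _record(chrom="chr1", pos=100, ref="A", alt="G", pg="0/0", py="1/1",
            gpool=(20, 10), ypool=(5, 25), gq=99, pool_gq=None):
    pool_gq = gq if pool_gq is None else pool_gq
    calls = {
        ROLES.parent_green: SampleCall(gt=pg, ad=(30, 0) if pg == "0/0" else (0, 30),
                                       gq=gq),
        ROLES.parent_yellow: SampleCall(gt=py, ad=(0, 30) if py == "1/1" else (30, 0),
                                        gq=gq),
        ROLES.pool_green: SampleCall(gt="0/1", ad=gpool, gq=pool_gq),
        ROLES.pool_yellow: SampleCall(gt="0/1", ad=ypool, gq=pool_gq),
    }
    return VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt, calls=calls)


class TestPoolCounts:
    def test_proportions_sum_to_one(self):
        p = PoolCounts(3, 7, ref_base="A", alt_base="G").proportions()
        assert p == {"A": 0.3, "G": 0.7}
        assert sum(p.values()) == pytest.approx(1.0)

    def test_zero_depth_undefined(self):
        with pytest.raises(UndefinedValueError):
            PoolCounts(0, 0, label="green").proportions()

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            PoolCounts(-1, 5)


class TestSnpIndex:
    def test_half(self):
        assert snp_index(PoolCounts(5, 5)) == pytest.approx(0.5)

    def test_one(self):
        assert snp_index(PoolCounts(0, 37)) == pytest.approx(1.0)

    def test_quarter(self):
        assert snp_index(PoolCounts(30, 10)) == pytest.approx(0.25)

    def test_zero_depth(self):
        with pytest.raises(UndefinedValueError, match="green"):
            snp_index(PoolCounts(0, 0, label="green"))


class TestDeltaSnpIndex:
    def test_worked_example(self):
        # yellow (0,40) -> 1.0; green (27,13) -> 0.325
        assert delta_snp_index(PoolCounts(27, 13), PoolCounts(0, 40)) == \
            pytest.approx(0.675)

    def test_identical_pools(self):
        assert delta_snp_index(PoolCounts(9, 3), PoolCounts(9, 3)) == 0.0

    def test_fully_linked_infinite_depth(self):
        # Conditional F2 frequencies: yellow index 1, green index 1/3.
        green = PoolCounts(2_000_000, 1_000_000)
        yellow = PoolCounts(0, 3_000_000)
        assert delta_snp_index(green, yellow) == pytest.approx(2 / 3)


class TestEd2:
    def test_opposite_fixed(self):
        g = PoolCounts(40, 0, ref_base="A", alt_base="G")
        y = PoolCounts(0, 40, ref_base="A", alt_base="G")
        assert ed2(g, y) == pytest.approx(2.0)

    def test_identical(self):
        g = PoolCounts(10, 30, ref_base="A", alt_base="G")
        y = PoolCounts(5, 15, ref_base="A", alt_base="G")
        assert ed2(g, y) == pytest.approx(0.0)

    def test_fully_linked_infinite_depth(self):
        g = PoolCounts(2_000_000, 1_000_000, ref_base="C", alt_base="T")
        y = PoolCounts(0, 3_000_000, ref_base="C", alt_base="T")
        assert ed2(g, y) == pytest.approx(8 / 9)

    def test_indel_pseudo_bases(self):
        g = PoolCounts(40, 0)  # default ref/alt pseudo-bases
        y = PoolCounts(0, 40)
        assert ed2(g, y) == pytest.approx(2.0)


depths = st.integers(min_value=0, max_value=500)


@settings(max_examples=200, deadline=None)
@given(gr=depths, ga=depths, yr=depths, ya=depths)
def test_statistic_bounds_and_biallelic_identity(gr, ga, yr, ya):
    if gr + ga == 0 or yr + ya == 0:
        return
    g = PoolCounts(gr, ga, ref_base="A", alt_base="G")
    y = PoolCounts(yr, ya, ref_base="A", alt_base="G")
    ig, iy = snp_index(g), snp_index(y)
    d = delta_snp_index(g, y)
    e = ed2(g, y)
    assert 0.0 <= ig <= 1.0 and 0.0 <= iy <= 1.0
    assert -1.0 <= d <= 1.0
    assert 0.0 <= e <= 2.0
    # biallelic identity: ED^2 == 2 * (alt-proportion difference)^2
    assert e == pytest.approx(2.0 * (iy - ig) ** 2, abs=1e-12)


class TestFilterVariants:
    def test_pass_example(self):
        passing, report = filter_variants([_record()])
        assert len(passing) == 1
        assert report.n_pass == 1 and report.n_input == 1

    def test_parent_het_removed(self):
        rec = _record(pg="0/1")
        passing, report = filter_variants([rec])
        assert passing == [] and report.n_removed["parent_het"] == 1

    def test_pool_missing_removed(self):
        rec = _record(ypool=(0, 0))
        passing, report = filter_variants([rec])
        assert passing == [] and report.n_removed["pool_missing"] == 1

    def test_low_gq_removed(self):
        rec = _record(gq=20)
        passing, report = filter_variants([rec])
        assert passing == [] and report.n_removed["low_gq"] == 1

    def test_parent_monomorphic_removed(self):
        rec = _record(pg="1/1", py="1/1")
        passing, report = filter_variants([rec])
        assert passing == [] and report.n_removed["parent_monomorphic"] == 1

    def test_first_fail_attribution(self):
        # Fails both low_gq and parent_het; attributed to low_gq only.
        rec = _record(pg="0/1", gq=10)
        _, report = filter_variants([rec])
        assert report.n_removed["low_gq"] == 1
        assert report.n_removed["parent_het"] == 0

    def test_missing_sample_names_role(self):
        rec = _record()
        del rec.calls[ROLES.pool_yellow]
        with pytest.raises(BulkmapError, match="pool_yellow"):
            filter_variants([rec])

    def test_report_invariant(self):
        records = [_record(pos=p) for p in (100, 200)]
        records += [_record(pos=300, pg="0/1"), _record(pos=400, gq=5)]
        _, report = filter_variants(records)
        report.check()
        assert report.n_input == 4 and report.n_pass == 2
        assert set(report.n_removed) == set(FILTER_RULES)


def _site_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "snp_index_green",
                                       "snp_index_yellow", "delta_snp_index",
                                       "ed2", "depth_green", "depth_yellow"])


class TestSlidingWindows:
    def test_mean_example(self):
        df = _site_df([("chr1", 50_000, 0, 0, 0.4, 0.32, 30, 30),
                       ("chr1", 150_000, 0, 0, 0.6, 0.72, 30, 30)])
        win = sliding_windows(df, chrom_lengths={"chr1": 200_000})
        first = win.iloc[0]
        assert (first["start"], first["end"]) == (1, 200_000)
        assert first["mean_delta"] == pytest.approx(0.5)
        assert first["mean_ed2"] == pytest.approx(0.52)
        assert first["n_sites"] == 2

    def test_site_in_exactly_two_interior_windows(self):
        df = _site_df([("chr1", 150_001, 0, 0, 0.4, 0.32, 30, 30)])
        win = sliding_windows(df, chrom_lengths={"chr1": 1_000_000})
        containing = win[win["n_sites"] > 0]
        assert sorted(containing["start"]) == [1, 100_001]

    def test_empty_chromosome_all_null(self):
        df = _site_df([("chr1", 50_000, 0, 0, 0.4, 0.32, 30, 30)])
        win = sliding_windows(df, chrom_lengths={"chr1": 300_000,
                                                 "chr2": 300_000})
        chr2 = win[win["chrom"] == "chr2"]
        assert len(chr2) == 3
        assert chr2["mean_delta"].isna().all()
        assert not chr2["sig95"].any() and not chr2["sig99"].any()

    def test_truncated_last_window(self):
        df = _site_df([("chr1", 250_000, 0, 0, 0.4, 0.32, 30, 30)])
        win = sliding_windows(df, chrom_lengths={"chr1": 250_000})
        assert int(win.iloc[-1]["end"]) == 250_000

    def test_unsorted_rejected(self):
        df = _site_df([("chr1", 150_000, 0, 0, 0.4, 0.32, 30, 30),
                       ("chr1", 50_000, 0, 0, 0.6, 0.72, 30, 30)])
        with pytest.raises(ValueError, match="sorted"):
            sliding_windows(df)

    def test_interleaved_chroms_rejected(self):
        df = _site_df([("chr1", 100, 0, 0, 0.1, 0.02, 30, 30),
                       ("chr2", 100, 0, 0, 0.1, 0.02, 30, 30),
                       ("chr1", 200, 0, 0, 0.1, 0.02, 30, 30)])
        with pytest.raises(ValueError, match="sorted"):
            sliding_windows(df)

    def test_min_sites_nulls(self):
        df = _site_df([("chr1", 50_000, 0, 0, 0.4, 0.32, 30, 30)])
        win = sliding_windows(df, min_sites=2, chrom_lengths={"chr1": 200_000})
        assert win["mean_delta"].isna().all()
        assert (win["n_sites"] >= 0).all()

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        pos = np.sort(rng.integers(1, 2_000_000, size=300))
        delta = rng.uniform(-1, 1, size=300)
        e = rng.uniform(0, 2, size=300)
        df = _site_df([("chr1", int(p), 0, 0, d, v, 30, 30)
                       for p, d, v in zip(pos, delta, e)])
        win = sliding_windows(df, chrom_lengths={"chr1": 2_000_000})
        for _, w in win.iterrows():
            mask = (pos >= w["start"]) & (pos <= w["end"])
            assert int(w["n_sites"]) == int(mask.sum())
            if mask.any():
                assert w["mean_delta"] == pytest.approx(delta[mask].mean())
                assert w["mean_ed2"] == pytest.approx(e[mask].mean())
            else:
                assert np.isnan(w["mean_delta"])


class TestNullThresholds:
    def test_quantile_monotone(self):
        thr = null_thresholds([np.full(10, 1000)], pool_size=30,
                              n_sims=2000, seed=1)
        assert thr.shape == (1, 2)
        assert thr[0, 0] < thr[0, 1]

    def test_thr99_below_linked_expectation(self):
        # depth 50, 20 sites/window, pool 30, n_sims 5000 -> thr99 < 2/3
        thr = null_thresholds([np.full(20, 50)], pool_size=30,
                              n_sims=5000, seed=7)
        assert thr[0, 1] < 2 / 3

    def test_monte_carlo_stability(self):
        depths = [np.full(20, 50)]
        a = null_thresholds(depths, pool_size=30, n_sims=2000, seed=3)
        b = null_thresholds(depths, pool_size=30, n_sims=4000, seed=3)
        assert np.all(np.abs(a - b) < 0.02)

    def test_deterministic_under_seed(self):
        depths = [np.full(5, 40), np.full(8, 60)]
        a = null_thresholds(depths, n_sims=1000, seed=11)
        b = null_thresholds(depths, n_sims=1000, seed=11)
        assert np.array_equal(a, b)

    def test_zero_depth_error(self):
        with pytest.raises(ValueError, match="depth"):
            null_thresholds([np.array([10, 0])], n_sims=1000, seed=1)

    def test_n_sims_floor(self):
        with pytest.raises(ValueError, match="n_sims"):
            null_thresholds([np.full(5, 40)], n_sims=500, seed=1)

    def test_empty_window_nan(self):
        thr = null_thresholds([np.array([], dtype=int), np.full(5, 40)],
                              n_sims=1000, seed=1)
        assert np.isnan(thr[0]).all() and not np.isnan(thr[1]).any()


def _win_df(rows):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_sites",
                                     "mean_delta", "mean_ed2"])
    df["sig95"] = False
    df["sig99"] = False
    return df


class TestCallPeaks:
    def test_merge_three_overlapping(self):
        win = _win_df([("chr1", 1, 200_000, 5, 0.7, 0.9),
                       ("chr1", 100_001, 300_000, 5, 0.8, 1.0),
                       ("chr1", 200_001, 400_000, 5, 0.75, 0.95)])
        peaks = call_peaks(win, thresholds=(0.4, 0.5))
        assert len(peaks) == 1
        iv = peaks[0].interval
        assert (iv.start, iv.end) == (1, 400_000)
        assert peaks[0].max_mean_delta == pytest.approx(0.8)
        assert peaks[0].peak_window.start == 100_001

    def test_no_significant_windows(self):
        win = _win_df([("chr1", 1, 200_000, 5, 0.1, 0.02)])
        assert call_peaks(win, thresholds=(0.4, 0.5)) == []

    def test_distinct_runs_not_merged_without_gap(self):
        win = _win_df([("chr1", 1, 200_000, 5, 0.7, 0.9),
                       ("chr1", 900_001, 1_100_000, 5, 0.8, 1.0)])
        peaks = call_peaks(win, thresholds=(0.4, 0.5), merge_gap_bp=0)
        assert len(peaks) == 2

    def test_merge_gap_fuses_nearby_runs(self):
        win = _win_df([("chr1", 1, 200_000, 5, 0.7, 0.9),
                       ("chr1", 900_001, 1_100_000, 5, 0.8, 1.0)])
        peaks = call_peaks(win, thresholds=(0.4, 0.5), merge_gap_bp=2_000_000)
        assert len(peaks) == 1
        assert peaks[0].interval.end == 1_100_000

    def test_level_95_vs_99(self):
        win = _win_df([("chr1", 1, 200_000, 5, 0.45, 0.5)])
        assert call_peaks(win, thresholds=(0.4, 0.5), level=99) == []
        assert len(call_peaks(win, thresholds=(0.4, 0.5), level=95)) == 1

    def test_nan_windows_never_significant(self):
        win = _win_df([("chr1", 1, 200_000, 0, np.nan, np.nan)])
        out = annotate_significance(win, 0.1, 0.2)
        assert not out["sig95"].any() and not out["sig99"].any()

    def test_require_ed2(self):
        win = _win_df([("chr1", 1, 200_000, 5, 0.7, 0.1)])
        assert call_peaks(win, thresholds=(0.4, 0.5), require_ed2=True) == []


class TestQuantileThresholds:
    def test_matches_numpy_quantile(self):
        rng = np.random.default_rng(0)
        win = _win_df([("chr1", 1 + i, 10 + i, 1, d, 0.0)
                       for i, d in enumerate(rng.uniform(-1, 1, 200))])
        thr = quantile_thresholds(win)
        expect = np.quantile(np.abs(win["mean_delta"]), [0.95, 0.99])
        assert np.allclose(thr, expect)

    def test_all_nan_error(self):
        win = _win_df([("chr1", 1, 10, 0, np.nan, np.nan)])
        with pytest.raises(ValueError):
            quantile_thresholds(win)


# ---------------------------------------------------------------------------
# End-to-end scan on simulated data
# ---------------------------------------------------------------------------

REDUCED = bm.SimConfig(n_chromosomes=3, chrom_length_bp=10_000_000,
                       chrom_length_cM=50.0, n_variants_per_chrom=1200,
                       n_f2=120, bulk_size=20, mean_depth=54.0,
                       causal_chrom=1, causal_pos_bp=5_000_000, seed=0)


class TestScanModel:
    def test_recovery_default_config_single_replicate(self):
        rep = bm.run_replicate(2026)
        results = rep["results"]
        assert len(results.peaks) == 1
        iv = results.peaks[0].interval
        assert iv.chrom == "chr6"
        assert iv.contains("chr6", 23_800_000)
        # fully linked causal expectations dominate the peak window
        assert results.peaks[0].max_mean_delta > 0.5
        assert results.peaks[0].max_mean_ed2 > 0.5

    def test_summary_and_save(self, tmp_path):
        rep = bm.run_replicate(5, REDUCED)
        results = rep["results"]
        text = results.summary()
        assert "Bulked-segregant scan" in text
        assert "called peak intervals" in text
        paths = results.save(tmp_path / "scan")
        for p in paths.values():
            assert (tmp_path / p).exists() or p  # absolute path strings
        win = pd.read_csv(paths["windows"], sep="\t")
        assert {"chrom", "start", "end", "mean_delta", "sig99"} <= set(win.columns)

    def test_simulate_mode_runs(self):
        rep = bm.run_replicate(9, REDUCED, threshold_mode="simulate",
                               n_sims=1000)
        thr = rep["results"].thresholds
        assert thr["mode"] == "simulate"
        assert np.ndim(thr["thr99"]) == 1

    def test_window_site_depths_alignment(self):
        rep = bm.run_replicate(9, REDUCED)
        results = rep["results"]
        depths = window_site_depths(results.sites, results.windows)
        assert len(depths) == len(results.windows)
        n_sites = results.windows["n_sites"].to_numpy()
        assert all(len(d) == n for d, n in zip(depths, n_sites))

    def test_depth_monotonicity_median_width(self):
        # Spec invariant at reduced scale: more depth never widens the
        # median called interval.
        medians = []
        for depth in (10.0, 54.0, 500.0):
            cfg = REDUCED.with_(mean_depth=depth)
            widths = []
            for seed in range(12):
                rep = bm.run_replicate(seed, cfg)
                peaks = rep["results"].peaks
                if peaks:
                    primary = max(peaks, key=lambda p: p.max_mean_delta)
                    widths.append(primary.interval.width_bp)
            assert widths, f"no peaks called at depth {depth}"
            medians.append(float(np.median(widths)))
        assert medians[0] >= medians[1] >= medians[2] - 1


class TestSiteStatistics:
    def test_columns_and_values(self):
        df = site_statistics([_record(gpool=(30, 10), ypool=(0, 40))])
        row = df.iloc[0]
        assert row["snp_index_green"] == pytest.approx(0.25)
        assert row["snp_index_yellow"] == pytest.approx(1.0)
        assert row["delta_snp_index"] == pytest.approx(0.75)
        assert row["ed2"] == pytest.approx(2 * 0.75 ** 2)
        assert (row["depth_green"], row["depth_yellow"]) == (40, 40)
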
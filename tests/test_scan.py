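import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import bsaqtl as b
from bsaqtl import scan, sites


class TestSnpIndex:
    @pytest.mark.parametrize("b_reads, total, expected", [
        (20, 20, 1.0),   # every read from the late parent
        (0, 20, 0.0),    # every read from the early parent
        (7, 20, 0.35),
    ])
    def test_values(self, b_reads, total, expected):
        assert scan.snp_index(b_reads, total) == pytest.approx(expected)

    def test_zero_depth_is_missing(self):
        assert np.isnan(scan.snp_index(0, 0))

    @pytest.mark.parametrize("lf, ef, expected", [
        (0.9, 0.1, 0.8), (0.5, 0.5, 0.0), (0.0, 1.0, -1.0),
    ])
    def test_delta(self, lf, ef, expected):
        assert scan.delta_snp_index(lf, ef) == pytest.approx(expected)

    def test_delta_missing_propagates(self):
        assert np.isnan(scan.delta_snp_index(np.nan, 0.4))

    @given(st.integers(0, 500), st.integers(0, 500))
    def test_bounds(self, b_reads, extra):
        idx = scan.snp_index(b_reads, b_reads + extra)
        if b_reads + extra > 0:
            assert 0.0 <= idx <= 1.0

    def test_track_orients_to_parent_b_allele(self):
        # at the second site parent B carries REF, so REF reads are counted
        df = pd.DataFrame({
            "chrom": ["chr1", "chr1"], "pos": [100, 200],
            "vclass": "SNP", "indel_len": 0, "qual": 200.0,
            "pA_ref": [20, 0], "pA_alt": [0, 20],
            "pB_ref": [0, 20], "pB_alt": [20, 0],
            "ef_ref": [10, 30], "ef_alt": [30, 10],
            "lf_ref": [40, 0], "lf_alt": [0, 40],
        })
        track = scan.index_track(df)
        assert track["index_ef"].tolist() == [0.75, 0.75]
        assert track["index_lf"].tolist() == [0.0, 0.0]


def window_frame(chrom, positions, deltas):
    return pd.DataFrame({"chrom": chrom, "pos": positions,
                         "index_ef": 0.5, "index_lf": 0.5, "delta": deltas})


class TestWindowTrack:
    def test_single_site_window(self):
        track = window_frame("chr1", [5000], [0.42])
        w = scan.window_track(track, window_bp=10_000, step_bp=10_000,
                              min_sites=1)
        assert w.loc[w["n_sites"] == 1, "delta_mean"].iloc[0] == pytest.approx(0.42)

    def test_mean_of_two_sites(self):
        track = window_frame("chr1", [1000, 2000], [0.2, 0.4])
        w = scan.window_track(track, window_bp=10_000, step_bp=10_000,
                              min_sites=1)
        assert w["delta_mean"].iloc[0] == pytest.approx(0.3)

    def test_min_sites_masks_window(self):
        track = window_frame("chr1", [1000, 2000], [0.2, 0.4])
        w = scan.window_track(track, window_bp=10_000, step_bp=10_000,
                              min_sites=3)
        assert w["delta_mean"].isna().all()

    def test_window_mean_bounded_by_site_extreme(self, rng):
        pos = np.sort(rng.choice(np.arange(1, 3_000_000), 150, replace=False))
        deltas = rng.uniform(-1, 1, 150)
        track = window_frame("chr1", pos, deltas)
        w = scan.window_track(track, window_bp=500_000, step_bp=50_000,
                              min_sites=1).dropna()
        assert (w["delta_mean"].abs() <= np.abs(deltas).max() + 1e-12).all()
        assert (w["delta_mean"].abs() <= 1.0 + 1e-12).all()

    def test_step_larger_than_window_rejected(self):
        track = window_frame("chr1", [1000], [0.1])
        with pytest.raises(ValueError):
            scan.window_track(track, window_bp=1000, step_bp=2000)


class TestPermutationThreshold:
    def test_degenerate_maxima(self):
        assert scan.threshold_from_maxima(np.full(500, 0.123), 0.05) == 0.123

    def test_monotone_in_alpha(self, filtered_sites):
        thrs = [scan.permutation_threshold(filtered_sites, n_perm=300, seed=3,
                                           alpha=a, null="reads").value
                for a in (0.01, 0.05, 0.10)]
        assert thrs[0] >= thrs[1] >= thrs[2]

    def test_reads_null_study_cross_below_035(self, filtered_sites):
        thr = scan.permutation_threshold(filtered_sites, n_perm=1000, seed=5,
                                         null="reads")
        assert thr.value < 0.35

    def test_reads_null_against_independent_oracle(self, filtered_sites):
        """Cross-check the read-resampling null on a non-overlapping grid
        against a naively coded Monte-Carlo estimate of the same quantile."""
        kw = dict(window_bp=1_000_000, step_bp=1_000_000, min_sites=3)
        thr = scan.permutation_threshold(filtered_sites, n_perm=2000, seed=5,
                                         null="reads", **kw)
        ef = (filtered_sites["ef_ref"] + filtered_sites["ef_alt"]).to_numpy()
        lf = (filtered_sites["lf_ref"] + filtered_sites["lf_alt"]).to_numpy()
        chrom = filtered_sites["chrom"].to_numpy()
        pos = filtered_sites["pos"].to_numpy()
        windows = []
        for c in pd.unique(chrom):
            p = pos[chrom == c]
            idx = np.nonzero(chrom == c)[0]
            for s0 in range(0, int(p.max()) + 1, 1_000_000):
                sel = idx[(pos[idx] >= s0) & (pos[idx] < s0 + 1_000_000)]
                if len(sel) >= 3:
                    windows.append(sel)
        rng = np.random.default_rng(1234)
        maxima = np.empty(2000)
        for i in range(2000):
            d = rng.binomial(lf, 0.5) / lf - rng.binomial(ef, 0.5) / ef
            maxima[i] = max(abs(d[w].mean()) for w in windows)
        oracle = np.quantile(maxima, 0.95, method="higher")
        assert thr.value == pytest.approx(oracle, abs=0.02)

    def test_genedrop_exceeds_reads_null(self, study_cross_experiment,
                                         filtered_sites):
        # bulk-composition variance adds to read noise, so the gene-drop
        # threshold must be markedly higher
        cfg = study_cross_experiment.config
        gd = scan.genedrop_from_map(filtered_sites, cfg.marker_map,
                                    (cfg.n_early, cfg.n_late), cfg.error_rate)
        t_gene = scan.permutation_threshold(filtered_sites, n_perm=300, seed=7,
                                            null="genedrop", genedrop=gd)
        t_read = scan.permutation_threshold(filtered_sites, n_perm=300, seed=7,
                                            null="reads")
        assert t_gene.value > 1.5 * t_read.value

    def test_deterministic_given_seed(self, filtered_sites):
        a = scan.permutation_threshold(filtered_sites, n_perm=200, seed=9,
                                       null="reads")
        c = scan.permutation_threshold(filtered_sites, n_perm=200, seed=9,
                                       null="reads")
        assert a.value == c.value

    def test_all_uncovered_rejected(self, toy_site_table):
        empty = toy_site_table.assign(ef_ref=0, ef_alt=0)
        with pytest.raises(ValueError):
            scan.permutation_threshold(empty, null="reads")


def windows_from(deltas, chrom="chr1", step=10_000, window=10_000):
    starts = np.arange(len(deltas)) * step
    return pd.DataFrame({"chrom": chrom, "start": starts,
                         "end": starts + window, "n_sites": 5,
                         "delta_mean": deltas})


class TestCallRegions:
    def test_nothing_above_threshold(self):
        w = windows_from([0.1, 0.2, 0.15])
        assert scan.call_regions(w, 0.5) == []

    def test_single_block_peak(self):
        w = windows_from([0.1, 0.6, 0.7, 0.9, 0.65, 0.6, 0.1])
        regions = scan.call_regions(w, 0.5)
        assert len(regions) == 1
        r = regions[0]
        assert r.peak_delta == pytest.approx(0.9)
        assert r.start == 10_000 and r.end == 50_000 + 10_000
        assert r.n_windows == 5 and r.sign == 1

    def test_gap_of_three_windows_splits(self):
        # two blocks separated by 3 sub-threshold windows, merge_gap 1
        w = windows_from([0.8, 0.8, 0.1, 0.1, 0.1, 0.8, 0.8])
        regions = scan.call_regions(w, 0.5, merge_gap=1, merge_span_bp=0)
        assert len(regions) == 2

    def test_gap_of_one_window_bridged(self):
        w = windows_from([0.8, 0.8, 0.1, 0.8, 0.8])
        regions = scan.call_regions(w, 0.5, merge_gap=1, merge_span_bp=0)
        assert len(regions) == 1 and regions[0].n_windows == 4

    def test_opposite_signs_never_merge(self):
        w = windows_from([0.8, 0.8, -0.8, -0.8])
        regions = scan.call_regions(w, 0.5, merge_span_bp=0)
        assert [r.sign for r in regions] == [1, -1]

    def test_nearby_same_sign_regions_coalesce(self):
        w = windows_from([0.8, 0.8, 0.1, 0.1, 0.1, 0.8, 0.8])
        regions = scan.call_regions(w, 0.5, merge_gap=1,
                                    merge_span_bp=1_000_000)
        assert len(regions) == 1

    def test_masked_windows_do_not_qualify(self):
        w = windows_from([0.8, np.nan, 0.8])
        regions = scan.call_regions(w, 0.5, merge_gap=0, merge_span_bp=0)
        assert len(regions) == 2

    def test_bed_output(self, tmp_path):
        w = windows_from([0.8, 0.8, 0.1])
        regions = scan.call_regions(w, 0.5)
        path = tmp_path / "regions.bed"
        scan.regions_to_bed(regions, path)
        fields = path.read_text().strip().split("\t")
        assert fields[0] == "chr1" and fields[5] == "+"
        assert int(fields[1]) < int(fields[2])


class TestQtlRecovery:
    def test_planted_loci_recovered_with_correct_sign(self, study_cross_experiment):
        from bsaqtl import pipeline
        res = pipeline.scan_simulated(study_cross_experiment, n_perm=500)
        cfg = study_cross_experiment.config
        for q in cfg.qtls:
            pos_bp = cfg.marker_map.chrom_table(q.chrom)["pos_bp"].to_numpy()[
                np.argmin(np.abs(cfg.marker_map.chrom_table(q.chrom)["cm"].to_numpy() - q.cm))]
            hit = [r for r in res.regions
                   if r.chrom == q.chrom and r.start <= pos_bp <= r.end]
            assert hit, f"planted locus on {q.chrom} not covered"
            assert hit[0].sign == 1  # parent-B allele delays flowering
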
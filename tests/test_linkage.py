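import numpy as np
import pandas as pd
import pytest
from scipy import stats

import bsaqtl as b
from bsaqtl import genmap, linkage, simulate

from _oracles import lstsq_lod


class TestPairwiseLinkage:
    def test_identical_vectors(self):
        g = np.array([0, 0, 2, 2, 0, 2] * 5)
        R, p, n = linkage.pairwise_linkage(g, g)
        assert R == 0.0 and p < 1e-6

    def test_printed_eight_line_toy(self):
        # AA/AA, AA/AA, BB/BB, BB/BB, AA/BB, BB/AA, AA/AA, BB/BB
        gi = np.array([0, 0, 2, 2, 0, 2, 0, 2])
        gj = np.array([0, 0, 2, 2, 2, 0, 0, 2])
        R, p, n = linkage.pairwise_linkage(gi, gj, min_lines=8)
        assert R == pytest.approx(2 / 8)
        assert n == 8

    def test_independent_markers_near_half(self, rng):
        g1 = rng.choice([0, 2], 500)
        g2 = rng.choice([0, 2], 500)
        R, p, n = linkage.pairwise_linkage(g1, g2)
        assert abs(R - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_heterozygotes_excluded(self):
        gi = np.array([0, 1, 2, 0, 2] * 8)
        gj = np.array([0, 0, 2, 0, 2] * 8)
        R, p, n = linkage.pairwise_linkage(gi, gj)
        assert n == 32  # het rows dropped

    def test_single_class_flagged(self):
        gi = np.zeros(40)
        gj = np.array([0, 2] * 20)
        R, p, n = linkage.pairwise_linkage(gi, gj)
        assert np.isnan(R) and np.isnan(p)


class TestGrouping:
    def _pmatrix(self, vals, names):
        return pd.DataFrame(vals, index=names, columns=names)

    def test_all_unlinked(self):
        P = self._pmatrix(np.ones((3, 3)), list("ABC"))
        groups = linkage.group_markers(P)
        assert sorted(len(g) for g in groups) == [1, 1, 1]

    def test_single_linkage_chain(self):
        P = self._pmatrix(np.ones((3, 3)), list("ABC"))
        P.loc["A", "B"] = P.loc["B", "A"] = 1e-5
        P.loc["B", "C"] = P.loc["C", "B"] = 1e-5  # A-C unlinked directly
        groups = linkage.group_markers(P)
        assert sorted(groups[0]) == ["A", "B", "C"]

    def test_two_chromosomes_recovered(self):
        # simulated null crosses: the sparse marker panel should split into
        # its two chromosomes in nearly every replicate
        hits = 0
        for s in range(50):
            cfg = simulate.null_cross(100 + s)
            pop = simulate.simulate_cross(cfg)
            genos = pop.genotypes[simulate.linkage_subset(cfg.marker_map)]
            R, P = linkage.linkage_matrices(genos)
            hits += len(linkage.group_markers(P, R=R)) == 2
        assert hits >= 47  # >= 95% of 50 replicates


class TestOrdering:
    def test_three_marker_exhaustive(self):
        R = pd.DataFrame([[0, .05, .10], [.05, 0, .05], [.10, .05, 0]],
                         index=list("ABC"), columns=list("ABC"))
        order, obj = linkage.order_markers(R)
        assert order in (list("ABC"), list("CBA"))
        # exhaustive: sums over the three distinct orders
        assert obj == pytest.approx(0.10)

    def test_two_markers(self):
        R = pd.DataFrame([[0, .2], [.2, 0]], index=list("AB"), columns=list("AB"))
        order, obj = linkage.order_markers(R)
        assert sorted(order) == ["A", "B"] and obj == pytest.approx(0.2)

    def test_disconnected_rejected(self):
        R = pd.DataFrame([[0, np.nan, np.nan], [np.nan, 0, np.nan],
                          [np.nan, np.nan, 0]], index=list("ABC"),
                         columns=list("ABC"))
        with pytest.raises(ValueError):
            linkage.order_markers(R)

    def test_eleven_marker_chromosome_recovered(self):
        hits = 0
        for s in range(50):
            cfg = simulate.null_cross(300 + s)
            pop = simulate.simulate_cross(cfg)
            names = [m for m in simulate.linkage_subset(cfg.marker_map)
                     if m.startswith("chr1")]
            R, _ = linkage.linkage_matrices(pop.genotypes[names])
            order, _ = linkage.order_markers(R)
            hits += order in (names, names[::-1])
        assert hits >= 45  # >= 90% of 50 replicates


class TestBuildMap:
    def test_zero_fraction_zero_distance(self):
        R = pd.DataFrame([[0, 0.0], [0.0, 0]], index=list("AB"),
                         columns=list("AB"))
        m = linkage.build_map(["A", "B"], R)
        assert m["interval_cm"].iloc[1] == 0.0

    def test_sixth_fraction_matches_chain(self):
        R = pd.DataFrame([[0, 1 / 6], [1 / 6, 0]], index=list("AB"),
                         columns=list("AB"))
        m = linkage.build_map(["A", "B"], R)
        assert m["r"].iloc[1] == pytest.approx(0.1, abs=1e-12)
        assert m["interval_cm"].iloc[1] == pytest.approx(10.13662770270411, abs=1e-9)

    def test_total_length_is_sum_of_intervals(self):
        vals = np.array([[0, .1, .3], [.1, 0, .15], [.3, .15, 0]])
        R = pd.DataFrame(vals, index=list("ABC"), columns=list("ABC"))
        m = linkage.build_map(["A", "B", "C"], R)
        assert m["cum_cm"].iloc[-1] == pytest.approx(m["interval_cm"].iloc[1:].sum())

    def test_overlarge_fraction_clipped(self):
        R = pd.DataFrame([[0, 0.55], [0.55, 0]], index=list("AB"),
                         columns=list("AB"))
        with pytest.warns(UserWarning, match="clipped"):
            m = linkage.build_map(["A", "B"], R)
        assert np.isfinite(m["cum_cm"].iloc[-1])

    def test_estimated_length_matches_generating_map(self):
        # 20 cM interval, n = 213 lines: estimate within 3 SE of truth
        rows = [("chr1", "m1", 1, 0.0), ("chr1", "m2", 10_000_001, 20.0)]
        mm = simulate.MarkerMap(pd.DataFrame(rows, columns=["chrom", "marker",
                                                            "pos_bp", "cm"]))
        ests = []
        for s in range(30):
            cfg = simulate.CrossConfig(marker_map=mm, n_lines=213,
                                       generations=25, seed=600 + s)
            g = simulate.simulate_cross(cfg).genotypes
            R, _ = linkage.linkage_matrices(g)
            ests.append(linkage.build_map(["m1", "m2"], R)["cum_cm"].iloc[-1])
        R_true = genmap.ril_R_from_r(genmap.kosambi_r(20.0))
        se_R = np.sqrt(R_true * (1 - R_true) / 213)
        # delta method through the map chain, then shrink by the 30 replicates
        grad = (genmap.kosambi_cm(genmap.r_from_ril_R(R_true + 1e-5))
                - genmap.kosambi_cm(genmap.r_from_ril_R(R_true - 1e-5))) / 2e-5
        se = abs(grad) * se_R / np.sqrt(30)
        assert abs(np.mean(ests) - 20.0) < 3 * se


class TestMarkerScan:
    def test_toy_matches_least_squares_oracle(self):
        genos = pd.DataFrame({"m": [0, 0, 0, 0, 2, 2, 2, 2]})
        pheno = pd.Series([10, 10, 12, 12, 20, 20, 22, 22], dtype=float)
        res = linkage.marker_scan(genos, pheno)
        assert res["lod"].iloc[0] == pytest.approx(
            lstsq_lod(genos["m"], pheno), abs=1e-10)

    def test_null_scan_uniform_pvalues(self):
        cfg = simulate.null_cross(42)
        pop = simulate.simulate_cross(cfg)
        pop = simulate.assign_phenotypes(pop, cfg)
        genos = pop.genotypes[simulate.linkage_subset(cfg.marker_map)]
        res = linkage.marker_scan(genos, pop.phenotypes)
        assert res["lod"].median() < 0.5
        # markers are linked within chromosomes, so thin to one per chrom
        sub = res[res["marker"].isin(["chr1_m1", "chr2_m1"])]
        assert (sub["p"] > 0.001).all()
        ks = stats.kstest(res["p"], "uniform")
        assert ks.pvalue > 1e-4  # p-values not grossly non-uniform

    def test_exact_fit_capped_and_flagged(self):
        genos = pd.DataFrame({"m": [0, 0, 0, 2, 2, 2]})
        pheno = pd.Series([30.0, 30, 30, 40, 40, 40])
        res = linkage.marker_scan(genos, pheno)
        assert bool(res["flagged"].iloc[0])
        assert np.isfinite(res["lod"].iloc[0])

    def test_constant_phenotype_flagged(self):
        genos = pd.DataFrame({"m": [0, 0, 2, 2]})
        res = linkage.marker_scan(genos, pd.Series([5.0, 5, 5, 5]))
        assert bool(res["flagged"].iloc[0]) and np.isnan(res["F"].iloc[0])

    def test_top_marker_near_planted_qtl(self):
        hits = 0
        for s in range(20):
            cfg = b.study_cross(300 + s)
            pop = simulate.simulate_cross(cfg)
            pop = simulate.assign_phenotypes(pop, cfg)
            genos = pop.genotypes[simulate.linkage_subset(cfg.marker_map)]
            res = linkage.marker_scan(genos, pop.phenotypes).set_index("marker")
            cm_of = cfg.marker_map.table.set_index("marker")["cm"]
            ok = True
            for q in cfg.qtls:
                sub = res[res.index.str.startswith(q.chrom)]
                ok &= abs(cm_of[sub["lod"].idxmax()] - q.cm) <= 10
            hits += ok
        assert hits >= 18  # within 10 cM in >= 90% of replicates


@pytest.fixture(scope="module")
def null_data():
    cfg = simulate.null_cross(7)
    pop = simulate.simulate_cross(cfg)
    pop = simulate.assign_phenotypes(pop, cfg)
    return pop, cfg


class TestLodThreshold:
    def test_floor_applies_when_quantile_low(self, null_data):
        pop, cfg = null_data
        genos = pop.genotypes.iloc[:, :3]  # few markers: low quantile
        thr = linkage.lod_threshold(genos, pop.phenotypes, n_perm=300, seed=1)
        assert thr.quantile < 2.5 and thr.value == 2.5

    def test_quantile_used_when_above_floor(self, null_data):
        pop, cfg = null_data
        thr = linkage.lod_threshold(pop.genotypes, pop.phenotypes,
                                    n_perm=300, seed=1)
        assert thr.quantile > 2.5 and thr.value == thr.quantile

    def test_monotone_in_alpha(self, null_data):
        pop, cfg = null_data
        genos = pop.genotypes[simulate.linkage_subset(cfg.marker_map)]
        vals = [linkage.lod_threshold(genos, pop.phenotypes, n_perm=300,
                                      alpha=a, seed=2).quantile
                for a in (0.01, 0.05, 0.10)]
        assert vals[0] >= vals[1] >= vals[2]

    def test_few_replicates_warn(self, null_data):
        pop, cfg = null_data
        with pytest.warns(UserWarning):
            linkage.lod_threshold(pop.genotypes.iloc[:, :2], pop.phenotypes,
                                  n_perm=50, seed=3)

    def test_fast_scanner_matches_marker_scan(self, null_data):
        pop, cfg = null_data
        genos = pop.genotypes[simulate.linkage_subset(cfg.marker_map)]
        ref = linkage.marker_scan(genos, pop.phenotypes)
        fast = linkage._FastLodScanner(genos)
        got = fast.max_lod(pop.phenotypes.to_numpy()[None, :])[0]
        assert got == pytest.approx(ref["lod"].max(), abs=1e-9)
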
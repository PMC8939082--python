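"""Weir–Cockerham components, windowed F_ST, log2 pi ratio, outliers, regions."""

import itertools

import numpy as np
import pandas as pd
import pytest

from popsweep import pipeline
from popsweep.diversity import make_windows, windowed_pi
from popsweep.genotypes import PopulationMap
from popsweep.simulate import SimConfig, SweepSpec, simulate
from popsweep.sweep import (annotate_regions, call_candidate_regions,
                            empirical_outliers, intersect_regions,
                            log2_pi_ratio, merge_windows, site_components,
                            wc_site_components, windowed_weighted_fst)

from conftest import make_gm, two_group_popmap


def wc_oracle(genos_a, genos_b):
    """Independent scalar evaluation of the two-population variance
    components from raw diploid genotypes (dosage lists), written
    deliberately without arrays so it cannot share bugs with the
    vectorized implementation."""
    r = 2
    stats = []
    for g in (genos_a, genos_b):
        n = len(g)
        p = sum(g) / (2 * n)
        h = sum(1 for x in g if x == 1) / n
        stats.append((n, p, h))
    nsum = sum(s[0] for s in stats)
    nbar = nsum / r
    nc = (nsum - sum(s[0] ** 2 for s in stats) / nsum) / (r - 1)
    pbar = sum(s[0] * s[1] for s in stats) / nsum
    s2 = sum(s[0] * (s[1] - pbar) ** 2 for s in stats) / ((r - 1) * nbar)
    hbar = sum(s[0] * s[2] for s in stats) / nsum
    if pbar in (0.0, 1.0):
        return 0.0, 0.0, 0.0
    qbar = 1 - pbar
    a = (nbar / nc) * (s2 - (pbar * qbar - s2 / 2 - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * qbar - s2 / 2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


def _site(genos_a, genos_b):
    """WCComponents for one site given dosage lists for the two groups."""
    def stats(g):
        n = float(len(g))
        p = sum(g) / (2 * n)
        h = sum(1 for x in g if x == 1) / n
        return n, p, h
    na, pa, ha = stats(genos_a)
    nb, pb, hb = stats(genos_b)
    return wc_site_components(np.array([[na], [nb]]), np.array([[pa], [pb]]),
                              np.array([[ha], [hb]]))


class TestSiteComponents:
    def test_fixed_difference_is_one(self):
        comp = _site([0, 0], [2, 2])
        assert comp.a[0] == pytest.approx(0.5, abs=1e-12)
        assert comp.b[0] == pytest.approx(0.0, abs=1e-12)
        assert comp.c[0] == pytest.approx(0.0, abs=1e-12)
        fst = comp.a[0] / (comp.a[0] + comp.b[0] + comp.c[0])
        assert fst == pytest.approx(1.0, abs=1e-12)

    def test_hand_worked_two_thirds(self):
        comp = _site([0, 1], [2, 2])
        assert comp.a[0] == pytest.approx(0.25, abs=1e-12)
        assert comp.b[0] == pytest.approx(0.0, abs=1e-12)
        assert comp.c[0] == pytest.approx(0.125, abs=1e-12)
        fst = comp.a[0] / (comp.a[0] + comp.b[0] + comp.c[0])
        assert fst == pytest.approx(2 / 3, abs=1e-12)

    def test_identical_groups_negative_third(self):
        comp = _site([0, 1], [0, 1])
        assert comp.a[0] == pytest.approx(-0.0625, abs=1e-12)
        assert comp.b[0] == pytest.approx(0.0, abs=1e-12)
        assert comp.c[0] == pytest.approx(0.25, abs=1e-12)
        fst = comp.a[0] / (comp.a[0] + comp.b[0] + comp.c[0])
        assert fst == pytest.approx(-1 / 3, abs=1e-12)

    def test_exhaustive_two_diploids_per_group_oracle(self):
        """All 3^4 genotype configurations match the independent evaluation."""
        for ga in itertools.product([0, 1, 2], repeat=2):
            for gb in itertools.product([0, 1, 2], repeat=2):
                comp = _site(list(ga), list(gb))
                oa, ob, oc = wc_oracle(list(ga), list(gb))
                if comp.monomorphic[0]:
                    assert (oa, ob, oc) == (0.0, 0.0, 0.0)
                    continue
                assert comp.a[0] == pytest.approx(oa, abs=1e-12)
                assert comp.b[0] == pytest.approx(ob, abs=1e-12)
                assert comp.c[0] == pytest.approx(oc, abs=1e-12)

    def test_monomorphic_site_zeroed_and_excluded(self):
        comp = _site([0, 0], [0, 0])
        assert comp.monomorphic[0] and not comp.usable[0]
        assert comp.a[0] == 0.0 == comp.b[0] == comp.c[0]


class TestWindowedFst:
    def test_single_site_window(self):
        gm = make_gm([["0/0", "0/1", "1/1", "1/1"]], pos=[100],
                     contig_lengths={"chr1": 50_000})
        pm = two_group_popmap(gm)
        df, genome = windowed_weighted_fst(gm, pm, "nat", "com",
                                           make_windows({"chr1": 50_000}))
        assert df["fst"].iloc[0] == pytest.approx(2 / 3)
        assert genome == pytest.approx(2 / 3)

    def test_monomorphic_window_flagged(self):
        gm = make_gm([["0/0", "0/0", "0/0", "0/0"]], pos=[100],
                     contig_lengths={"chr1": 50_000})
        pm = two_group_popmap(gm)
        df, _ = windowed_weighted_fst(gm, pm, "nat", "com",
                                      make_windows({"chr1": 50_000}))
        assert df["no_usable_sites"].iloc[0]
        assert np.isnan(df["fst"].iloc[0])

    def test_superset_contrast_labels(self):
        gm = make_gm([["0/0", "0/1", "1/1", "1/1"]], pos=[100],
                     contig_lengths={"chr1": 50_000})
        pm = two_group_popmap(gm)
        df, genome = windowed_weighted_fst(
            gm, pm, "native", "commercial", make_windows({"chr1": 50_000}))
        assert genome == pytest.approx(2 / 3)

    def test_identical_labels_rejected(self):
        gm = make_gm([["0/0", "0/1", "1/1", "1/1"]])
        pm = two_group_popmap(gm)
        with pytest.raises(ValueError):
            windowed_weighted_fst(gm, pm, "nat", "nat",
                                  make_windows({"chr1": 1000}))

    def test_recovers_generator_divergence(self):
        cfg = SimConfig(n_diploids_per_pop=50, n_snps_per_chrom=20_000,
                        chrom_length=20_000_000, bn_F=0.2, seed=41)
        gm, pm, _ = simulate(cfg)
        _, genome = windowed_weighted_fst(
            gm, pm, "native", "commercial",
            make_windows({"chr1": cfg.chrom_length}))
        assert abs(genome - 0.2) < 0.02

    def test_ratio_of_sums_within_site_range_when_denoms_positive(self):
        cfg = SimConfig(seed=43, n_snps_per_chrom=500, chrom_length=500_000)
        gm, pm, _ = simulate(cfg)
        comp = site_components(gm, pm, "native", "commercial")
        abc = comp.a + comp.b + comp.c
        ok = comp.usable & (abc > 0)
        ratios = comp.a[ok] / abc[ok]
        total = comp.a[ok].sum() / abc[ok].sum()
        assert ratios.min() - 1e-12 <= total <= ratios.max() + 1e-12


class TestLog2Ratio:
    def _pi_pair(self, pa, pb):
        base = pd.DataFrame({"chrom": ["chr1"] * len(pa),
                             "start": np.arange(len(pa)) * 25_000 + 1,
                             "end": np.arange(len(pa)) * 25_000 + 50_000,
                             "index": np.arange(len(pa)),
                             "truncated": False})
        a = base.assign(group="a", n_snps=1, pi=pa)
        b = base.assign(group="b", n_snps=1, pi=pb)
        return a, b

    def test_equal_pi_gives_zero(self):
        a, b = self._pi_pair([1e-4], [1e-4])
        assert log2_pi_ratio(a, b)["log2_ratio"].iloc[0] == pytest.approx(0.0)

    def test_double_pi_gives_one(self):
        a, b = self._pi_pair([2e-4], [1e-4])
        assert log2_pi_ratio(a, b)["log2_ratio"].iloc[0] == pytest.approx(1.0)

    def test_zero_pi_flagged_excluded(self):
        a, b = self._pi_pair([1e-4, 2e-4], [0.0, 1e-4])
        out = log2_pi_ratio(a, b)
        assert out["zero_pi"].iloc[0] and np.isnan(out["log2_ratio"].iloc[0])
        assert not out["zero_pi"].iloc[1]

    def test_window_mismatch_rejected(self):
        a, _ = self._pi_pair([1e-4], [1e-4])
        _, b = self._pi_pair([1e-4, 1e-4], [1e-4, 1e-4])
        with pytest.raises(ValueError, match="window"):
            log2_pi_ratio(a, b)


class TestEmpiricalOutliers:
    def test_nearest_rank_convention(self):
        vals = np.arange(0.01, 1.005, 0.01)
        thr, flags = empirical_outliers(vals, 0.05)
        assert flags.sum() == 5
        assert thr == pytest.approx(0.96)
        assert set(np.round(vals[flags], 2)) == {0.96, 0.97, 0.98, 0.99, 1.0}

    def test_ceiling_flags_at_least_one(self):
        vals = np.arange(10, dtype=float)
        thr, flags = empirical_outliers(vals, 0.05)
        assert flags.sum() == 1 and flags[-1]

    def test_ties_broken_by_genomic_order(self):
        vals = np.concatenate([np.full(10, 5.0), np.arange(90, dtype=float)])
        thr, flags = empirical_outliers(vals, 0.05)
        assert flags.sum() == 5
        # the 10-way tie at the max (89, 88... no: max is 89) -- construct
        vals = np.concatenate([np.zeros(90), np.full(10, 7.0)])
        order = np.arange(100)
        thr, flags = empirical_outliers(vals, 0.05, order)
        assert flags.sum() == 5
        assert np.flatnonzero(flags).tolist() == [90, 91, 92, 93, 94]

    def test_all_equal_warns(self):
        with pytest.warns(UserWarning, match="equal"):
            thr, flags = empirical_outliers(np.ones(20), 0.1)
        assert flags.sum() == 2 and flags[0] and flags[1]

    def test_nan_never_flagged(self):
        vals = np.array([np.nan, 1.0, 2.0, np.nan, 3.0])
        thr, flags = empirical_outliers(vals, 0.3)
        assert flags.sum() == 1 and flags[4]


class TestRegions:
    def test_overlapping_windows_merge(self):
        df = pd.DataFrame({"chrom": ["chr1"] * 2, "start": [1, 25_001],
                           "end": [50_000, 75_000]})
        out = merge_windows(df, np.array([True, True]))
        assert out[["start", "end"]].values.tolist() == [[1, 75_000]]

    def test_disjoint_stay_separate(self):
        df = pd.DataFrame({"chrom": ["chr1"] * 2, "start": [1, 100_001],
                           "end": [50_000, 150_000]})
        out = merge_windows(df, np.array([True, True]))
        assert len(out) == 2

    def test_book_ended_merge(self):
        df = pd.DataFrame({"chrom": ["chr1"] * 2, "start": [1, 50_001],
                           "end": [50_000, 100_000]})
        out = merge_windows(df, np.array([True, True]))
        assert len(out) == 1

    def test_intersection(self):
        ra = pd.DataFrame({"chrom": ["chr1"], "start": [1],
                           "end": [60_000], "region_id": ["a"]})
        rb = pd.DataFrame({"chrom": ["chr1"], "start": [40_000],
                           "end": [100_000], "region_id": ["b"]})
        out = intersect_regions(ra, rb)
        assert out[["start", "end"]].values.tolist() == [[40_000, 60_000]]


class TestAnnotate:
    def _regions(self):
        return pd.DataFrame({"chrom": ["chr1"],
                             "start": [176_340_000], "end": [176_360_000],
                             "region_id": ["chr1:176340000-176360000"]})

    def test_overlapping_gene_reported(self):
        genes = pd.DataFrame({"chrom": ["chr1"], "start": [176_330_000],
                              "end": [176_365_000], "gene": ["HSPH1"]})
        out = annotate_regions(self._regions(), genes, "fst")
        assert out["gene"].tolist() == ["HSPH1"]
        assert out["overlap_bp"].iloc[0] == 20_001

    def test_region_without_gene_empty(self):
        genes = pd.DataFrame({"chrom": ["chr1"], "start": [1],
                              "end": [100], "gene": ["FAR"]})
        assert annotate_regions(self._regions(), genes).empty

    def test_gene_spanning_two_regions_one_row(self):
        regions = pd.DataFrame({
            "chrom": ["chr1"] * 2, "start": [100, 5000],
            "end": [1000, 6000], "region_id": ["r1", "r2"]})
        genes = pd.DataFrame({"chrom": ["chr1"], "start": [500],
                              "end": [5500], "gene": ["G"]})
        out = annotate_regions(regions, genes)
        assert len(out) == 1 and out["regions"].iloc[0] == "r1,r2"

    def test_unannotated_chromosome_warns(self):
        genes = pd.DataFrame({"chrom": ["chr2"], "start": [1],
                              "end": [100], "gene": ["G"]})
        with pytest.warns(UserWarning, match="chr1"):
            out = annotate_regions(self._regions(), genes)
        assert out.empty


def sweep_panel(seed=47):
    cfg = SimConfig(n_chroms=2, chrom_length=10_000_000,
                    n_snps_per_chrom=5_000, n_diploids_per_pop=25,
                    bn_F=0.1, seed=seed,
                    sweeps=[SweepSpec("chr1", 3_000_000, 3_150_000,
                                      "commercial", 0.9),
                            SweepSpec("chr2", 7_000_000, 7_150_000,
                                      "commercial", 0.9)])
    return cfg, *simulate(cfg)


class TestEndToEndScan:
    def test_planted_sweeps_found_and_budget_exact(self):
        cfg, gm, pm, truth = sweep_panel()
        scan_cfg = pipeline.ScanConfig()
        report = pipeline.run_scan(gm, pm, scan_cfg)
        import math
        assert report.n_flagged_fst == math.ceil(
            0.05 * report.n_windows_usable_fst)
        assert report.n_flagged_ratio == math.ceil(
            0.01 * report.n_windows_usable_ratio)
        for sw in truth.sweeps:
            hit = report.intersection[
                (report.intersection["chrom"] == sw.chrom)
                & (report.intersection["start"] <= sw.end)
                & (report.intersection["end"] >= sw.start)]
            assert len(hit) >= 1, sw

    def test_scan_invariant_to_sample_order(self):
        cfg, gm, pm, _ = sweep_panel()
        scan_cfg = pipeline.ScanConfig()
        r1 = pipeline.run_scan(gm, pm, scan_cfg)
        perm = list(np.random.default_rng(3).permutation(gm.n_samples))
        r2 = pipeline.run_scan(gm.take_samples(perm), pm, scan_cfg)
        pd.testing.assert_frame_equal(r1.window_stats, r2.window_stats)
        pd.testing.assert_frame_equal(r1.intersection, r2.intersection)
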
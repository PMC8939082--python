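"""VCF/popmap round trips and the post-calling site filters."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from popsweep import variant_io
from popsweep.genotypes import MISSING, PopmapError
from popsweep.variant_io import (VcfParseError, cluster_mask,
                                 filter_biallelic_and_clusters,
                                 filter_quality, read_popmap, read_vcf,
                                 write_popmap, write_vcf)

from conftest import make_gm


class TestVcfRoundTrip:
    def test_basic_dosages(self, tmp_path):
        gm = make_gm([["0/0", "0/1"], ["0/1", "1/1"], ["1|1", "0|0"]])
        p = tmp_path / "t.vcf"
        write_vcf(gm, p)
        back = read_vcf(p)
        assert back == gm
        assert back.dosage.tolist() == [[0, 1], [1, 2], [2, 0]]
        assert back.phased[2].all() and not back.phased[0].any()

    def test_missing_and_multiallelic(self, tmp_path):
        gm = make_gm([["./.", "0/1"], ["1/2", "0/2"]],
                     alt=[("C",), ("C", "T")])
        p = tmp_path / "t.vcf"
        write_vcf(gm, p)
        back = read_vcf(p)
        assert back == gm
        assert back.alleles[0, 0].tolist() == [MISSING, MISSING]
        assert back.dosage[0, 0] == MISSING
        assert back.is_biallelic.tolist() == [True, False]
        assert len(back.alt[1]) == 2

    def test_quality_fields_and_contigs(self, tmp_path):
        gm = make_gm([["0/0", "0/1"]], gq=[[42, 13]], mq=[37.5],
                     contig_lengths={"chr1": 100000})
        p = tmp_path / "t.vcf"
        write_vcf(gm, p)
        back = read_vcf(p)
        assert back == gm
        assert back.contig_lengths == {"chr1": 100000}

    def test_empty_matrix(self, tmp_path):
        gm = make_gm([], contig_lengths={"chr1": 500})
        gm.sample_ids = ["s1", "s2"]
        gm.alleles = np.empty((0, 2, 2), dtype=np.int8)
        gm.phased = np.empty((0, 2), dtype=bool)
        p = tmp_path / "t.vcf"
        write_vcf(gm, p)
        back = read_vcf(p)
        assert back.n_sites == 0 and back.sample_ids == ["s1", "s2"]

    def test_malformed_record_names_line(self, tmp_path):
        p = tmp_path / "bad.vcf"
        p.write_text("##fileformat=VCFv4.2\n"
                     '##FORMAT=<ID=GT,Number=1,Type=String,Description="G">\n'
                     "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
                     "chr1\tnotanumber\t.\tA\tC\t.\t.\t.\tGT\t0/1\n")
        with pytest.raises(VcfParseError, match="line"):
            read_vcf(p)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.data())
    def test_roundtrip_random(self, tmp_path_factory, data):
        n_sites = data.draw(st.integers(1, 8))
        n_samples = data.draw(st.integers(1, 4))
        gts = data.draw(st.lists(
            st.lists(st.sampled_from(
                ["0/0", "0/1", "1/1", "0|1", "1|0", "./."]),
                min_size=n_samples, max_size=n_samples),
            min_size=n_sites, max_size=n_sites))
        gm = make_gm(gts)
        p = tmp_path_factory.mktemp("rt") / "t.vcf"
        write_vcf(gm, p)
        assert read_vcf(p) == gm


class TestQualityFilter:
    def test_gq_boundary_masks_genotype(self):
        gm = make_gm([["0/1", "0/1"]], gq=[[39, 40]])
        out, counts = filter_quality(gm)
        assert out.n_sites == 1
        assert out.dosage[0, 0] == MISSING and out.dosage[0, 1] == 1
        assert counts.n_genotypes_masked == 1

    def test_mq_boundary_drops_site(self):
        gm = make_gm([["0/1"], ["0/1"]], mq=[24.0, 25.0])
        out, counts = filter_quality(gm)
        assert out.n_sites == 1 and out.pos[0] == 200
        assert counts.n_sites_removed == 1

    def test_identity_when_all_pass(self):
        gm = make_gm([["0/1", "1/1"]], gq=[[40, 99]], mq=[25.0])
        out, counts = filter_quality(gm)
        assert out == gm
        assert counts.n_sites_removed == 0 == counts.n_genotypes_masked

    def test_absent_fields_pass_unchanged(self):
        gm = make_gm([["0/1", "1/1"], ["0/0", "0/1"]])
        out, _ = filter_quality(gm)
        assert out == gm

    def test_idempotent(self):
        gm = make_gm([["0/1", "0/1"], ["1/1", "0/0"]],
                     gq=[[10, 50], [50, 50]], mq=[30.0, 10.0])
        once, _ = filter_quality(gm)
        twice, counts = filter_quality(once)
        assert twice == once
        assert counts.n_sites_removed == 0 == counts.n_genotypes_masked


class TestClusterFilter:
    def test_four_snps_in_ten_bp_all_removed(self):
        gm = make_gm([["0/1"]] * 4, pos=[100, 101, 103, 107])
        out, counts = filter_biallelic_and_clusters(gm)
        assert out.n_sites == 0
        assert counts.detail["sites_removed_cluster"] == 4

    def test_exactly_three_in_ten_bp_kept(self):
        gm = make_gm([["0/1"]] * 3, pos=[100, 104, 109])
        out, _ = filter_biallelic_and_clusters(gm)
        assert out.n_sites == 3

    def test_triallelic_removed(self):
        gm = make_gm([["0/1"], ["0/2"]], pos=[100, 5000],
                     alt=[("C",), ("C", "T")])
        out, counts = filter_biallelic_and_clusters(gm)
        assert out.n_sites == 1 and len(out.alt[0]) == 1
        assert counts.detail["sites_removed_multiallelic"] == 1

    def test_cluster_independent_of_chrom_interleaving(self):
        # same positions on two chromosomes do not form joint clusters
        gm = make_gm([["0/1"]] * 6, pos=[100, 101, 103, 100, 104, 109],
                     chrom=["chr1"] * 3 + ["chr2"] * 3)
        out, _ = filter_biallelic_and_clusters(gm)
        assert out.n_sites == 6

    def test_idempotent(self):
        gm = make_gm([["0/1"]] * 6, pos=[100, 101, 103, 107, 500, 900])
        once, _ = filter_biallelic_and_clusters(gm)
        twice, counts = filter_biallelic_and_clusters(once)
        assert twice == once and counts.n_sites_removed == 0

    def test_mask_flags_every_cluster_member(self):
        pos = np.array([10, 12, 13, 14, 40, 100])
        m = cluster_mask(np.asarray(["c"] * 6, dtype=object), pos)
        assert m.tolist() == [True, True, True, True, False, False]


class TestPopmap:
    def _write(self, tmp_path, text):
        p = tmp_path / "pm.tsv"
        p.write_text(text)
        return p

    def test_read_two_groups(self, tmp_path):
        p = self._write(tmp_path, "sample\tgroup\tsuperset\n"
                                  "s1\tYazd\tnative\ns2\tArian\tcommercial\n")
        pm = read_popmap(p)
        assert pm.groups == ["Yazd", "Arian"]
        assert pm.samples_of("native") == ["s1"]

    def test_unknown_superset_rejected(self, tmp_path):
        p = self._write(tmp_path, "sample\tgroup\tsuperset\ns1\tX\tbroiler\n")
        with pytest.raises(PopmapError, match="broiler"):
            read_popmap(p)

    def test_missing_column_named(self, tmp_path):
        p = self._write(tmp_path, "sample\tgroup\ns1\tX\n")
        with pytest.raises(PopmapError, match="superset"):
            read_popmap(p)

    def test_duplicate_sample(self, tmp_path):
        p = self._write(tmp_path, "sample\tgroup\tsuperset\n"
                                  "s1\tX\tnative\ns1\tY\tnative\n")
        with pytest.raises(PopmapError, match="twice"):
            read_popmap(p)

    def test_empty_file(self, tmp_path):
        p = self._write(tmp_path, "")
        with pytest.raises(PopmapError):
            read_popmap(p)

    def test_roundtrip(self, tmp_path):
        p = self._write(tmp_path, "sample\tgroup\tsuperset\n"
                                  "s1\tYazd\tnative\ns2\tArian\tcommercial\n")
        pm = read_popmap(p)
        q = tmp_path / "out.tsv"
        write_popmap(pm, q)
        assert read_popmap(q) == pm


def test_simulated_panel_roundtrip(small_panel, tmp_path):
    _, gm, _, _ = small_panel
    p = tmp_path / "panel.vcf"
    write_vcf(gm, p)
    assert read_vcf(p) == gm
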
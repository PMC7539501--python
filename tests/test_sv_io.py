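import numpy as np
import pytest

from svorchard import (AccessionPanel, read_genotype_vcf, read_gff3,
                       read_panel_tsv, read_sv_vcf, write_bed,
                       write_genotype_vcf, write_panel_tsv, write_sv_vcf)
from svorchard.sv_io import ValidationError, VcfFormatError

from conftest import make_matrix, make_sv

HEADER = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=100000>
##contig=<ID=chr2,length=100000>
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="t">
##INFO=<ID=END,Number=1,Type=Integer,Description="e">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="l">
##INFO=<ID=SU,Number=1,Type=Integer,Description="s">
##INFO=<ID=SR,Number=1,Type=Integer,Description="s">
##INFO=<ID=MATEID,Number=1,Type=String,Description="m">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def _vcf(tmp_path, body, name="in.vcf"):
    p = tmp_path / name
    p.write_text(HEADER + body)
    return p


class TestReadSvVcf:
    def test_field_mapping(self, tmp_path):
        p = _vcf(tmp_path,
                 "chr1\t10001\tsv1\tN\t<DEL>\t30\t.\tSVTYPE=DEL;END=12000;SU=8;SR=3\n")
        (r,) = read_sv_vcf(p, caller="lumpy")
        assert (r.svtype, r.start, r.end, r.svlen) == ("DEL", 10001, 12000, 1999)
        assert (r.qual, r.su, r.sr, r.caller) == (30.0, 8, 3, "lumpy")

    def test_empty_body(self, tmp_path):
        assert read_sv_vcf(_vcf(tmp_path, ""), caller="x") == []

    def test_missing_svtype_names_the_record(self, tmp_path):
        p = _vcf(tmp_path, "chr1\t500\tbad\tN\t<DEL>\t30\t.\tEND=900\n")
        with pytest.raises(VcfFormatError, match="record 1 .*chr1:500"):
            read_sv_vcf(p, caller="x")

    def test_unpaired_bnd_rejected(self, tmp_path):
        p = _vcf(tmp_path,
                 "chr1\t500\tb1\tN\tN[chr2:900[\t30\t.\tSVTYPE=BND;MATEID=b2\n")
        with pytest.raises(ValidationError, match="unpaired breakend b1"):
            read_sv_vcf(p, caller="x")

    def test_bnd_mates_linked_and_share_event(self, tmp_path):
        p = _vcf(tmp_path,
                 "chr1\t500\tb1\tN\tN[chr2:900[\t30\t.\tSVTYPE=BND;MATEID=b2\n"
                 "chr2\t900\tb2\tN\tN[chr1:500[\t30\t.\tSVTYPE=BND;MATEID=b1\n")
        a, b = read_sv_vcf(p, caller="x")
        assert (a.mate_chrom, a.mate_pos) == ("chr2", 900)
        assert a.event_id == b.event_id == "b1"


class TestRoundTrip:
    def test_sv_vcf_round_trip_identity(self, small_sim, tmp_path):
        for caller, recs in small_sim.callsets.items():
            path = tmp_path / f"{caller}.vcf"
            write_sv_vcf(recs, path, small_sim.contigs)
            again = read_sv_vcf(path, caller=caller)
            assert again == recs
            # write(read(f)) stable as well
            write_sv_vcf(again, tmp_path / "again.vcf", small_sim.contigs)
            assert read_sv_vcf(tmp_path / "again.vcf", caller=caller) == again

    def test_coordinates_bit_exact_at_contig_edges(self, tmp_path):
        contigs = {"contig1": 50_000}
        recs = [
            make_sv(id="first", start=1, end=120, svlen=119),
            make_sv(id="last", start=49_000, end=50_000, svlen=1_000),
        ]
        write_sv_vcf(recs, tmp_path / "edge.vcf", contigs)
        again = read_sv_vcf(tmp_path / "edge.vcf", caller="lumpy")
        assert [(r.start, r.end) for r in again] == [(1, 120), (49_000, 50_000)]

    def test_genotype_vcf_round_trip(self, small_sim, tmp_path):
        path = tmp_path / "geno.vcf"
        write_genotype_vcf(small_sim.sv_matrix, path, small_sim.contigs)
        again = read_genotype_vcf(path, small_sim.panel)
        assert np.array_equal(again.geno, small_sim.sv_matrix.geno)
        assert list(again.variants["pos"]) == list(small_sim.sv_matrix.variants["pos"])

    def test_panel_round_trip(self, small_sim, tmp_path):
        write_panel_tsv(small_sim.panel, tmp_path / "panel.tsv")
        again = read_panel_tsv(tmp_path / "panel.tsv")
        assert again.groups == small_sim.panel.groups
        assert np.allclose(again.phenotypes["trait"],
                           small_sim.panel.phenotypes["trait"])


class TestGff3:
    def _write(self, tmp_path, body):
        p = tmp_path / "g.gff3"
        p.write_text("##gff-version 3\n##sequence-region chr1 1 100000\n" + body)
        return p

    def test_plus_strand_promoter(self, tmp_path):
        p = self._write(tmp_path,
                        "chr1\tx\tgene\t10000\t12000\t.\t+\t.\tID=g1\n"
                        "chr1\tx\tmRNA\t10000\t12000\t.\t+\t.\tID=m1;Parent=g1\n"
                        "chr1\tx\tCDS\t10000\t12000\t.\t+\t0\tID=c1;Parent=m1\n")
        (g,) = read_gff3(p)
        assert g.promoter == (8000, 9999)

    def test_minus_strand_promoter(self, tmp_path):
        p = self._write(tmp_path,
                        "chr1\tx\tgene\t10000\t12000\t.\t-\t.\tID=g1\n"
                        "chr1\tx\tmRNA\t10000\t12000\t.\t-\t.\tID=m1;Parent=g1\n"
                        "chr1\tx\tCDS\t10000\t12000\t.\t-\t0\tID=c1;Parent=m1\n")
        (g,) = read_gff3(p)
        assert g.promoter == (12001, 14000)

    def test_intron_is_inter_cds_gap(self, tmp_path):
        p = self._write(tmp_path,
                        "chr1\tx\tgene\t10000\t12000\t.\t+\t.\tID=g1\n"
                        "chr1\tx\tmRNA\t10000\t12000\t.\t+\t.\tID=m1;Parent=g1\n"
                        "chr1\tx\tCDS\t10000\t10500\t.\t+\t0\tID=c1;Parent=m1\n"
                        "chr1\tx\tCDS\t11000\t12000\t.\t+\t0\tID=c2;Parent=m1\n")
        (g,) = read_gff3(p)
        assert g.introns == [(10501, 10999)]

    def test_cds_outside_span_rejected(self, tmp_path):
        p = self._write(tmp_path,
                        "chr1\tx\tgene\t10000\t12000\t.\t+\t.\tID=g1\n"
                        "chr1\tx\tmRNA\t10000\t12000\t.\t+\t.\tID=m1;Parent=g1\n"
                        "chr1\tx\tCDS\t9000\t10500\t.\t+\t0\tID=c1;Parent=m1\n")
        with pytest.raises(ValidationError, match="outside span"):
            read_gff3(p)

    def test_representative_transcript_is_longest_cds(self, tmp_path):
        p = self._write(tmp_path,
                        "chr1\tx\tgene\t10000\t12000\t.\t+\t.\tID=g1\n"
                        "chr1\tx\tmRNA\t10000\t12000\t.\t+\t.\tID=m1;Parent=g1\n"
                        "chr1\tx\tCDS\t10000\t10100\t.\t+\t0\tID=c1;Parent=m1\n"
                        "chr1\tx\tmRNA\t10000\t12000\t.\t+\t.\tID=m2;Parent=g1\n"
                        "chr1\tx\tCDS\t10000\t11500\t.\t+\t0\tID=c2;Parent=m2\n")
        (g,) = read_gff3(p)
        assert g.cds == [(10000, 11500)]

    def test_round_trip_through_generator_models(self, small_sim, tmp_path):
        from svorchard import write_gff3

        write_gff3(small_sim.genes, tmp_path / "genes.gff3", small_sim.contigs)
        again = read_gff3(tmp_path / "genes.gff3")
        assert again == small_sim.genes


class TestGenotypeVcf:
    GT_HEADER = HEADER.replace(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3")

    def _panel(self):
        return AccessionPanel(groups={"s1": "wild", "s2": "landrace",
                                      "s3": "improved"})

    def test_codes_and_missing_column_preserved(self, tmp_path):
        p = tmp_path / "g.vcf"
        p.write_text(self.GT_HEADER +
                     "chr1\t100\tv1\tA\tT\t.\t.\t.\tGT\t0/0\t0/1\t1/1\n"
                     "chr1\t200\tv2\tA\tT\t.\t.\t.\tGT\t./.\t./.\t./.\n")
        m = read_genotype_vcf(p, self._panel())
        assert m.geno.shape == (3, 2)
        assert list(m.geno[:, 0]) == [0, 1, 2]
        assert list(m.geno[:, 1]) == [-1, -1, -1]

    def test_unknown_sample_listed(self, tmp_path):
        p = tmp_path / "g.vcf"
        p.write_text(self.GT_HEADER +
                     "chr1\t100\tv1\tA\tT\t.\t.\t.\tGT\t0/0\t0/1\t1/1\n")
        panel = AccessionPanel(groups={"s1": "wild", "s2": "landrace"})
        with pytest.raises(ValidationError, match=r"\['s3'\]"):
            read_genotype_vcf(p, panel)


def test_panel_rejects_unknown_group():
    with pytest.raises(ValidationError, match="weedy"):
        AccessionPanel(groups={"a": "weedy"})


def test_bed_writer_converts_to_half_open(tmp_path):
    write_bed([("chr1", 1, 100), ("chr2", 501, 600, "sweep")],
              tmp_path / "x.bed")
    lines = (tmp_path / "x.bed").read_text().splitlines()
    assert lines == ["chr1\t0\t100", "chr2\t500\t600\tsweep"]
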
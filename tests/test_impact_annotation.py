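import numpy as np
import pytest

from svorchard import GeneModel, gene_level_summary, sv_gene_overlaps
from svorchard.impact_annotation import affected_gene_table

from conftest import make_sv


def gene(gene_id="g1", chrom="contig1", strand="+", start=10_000, end=12_000,
         cds=None, introns=None, promoter=None):
    if cds is None:
        cds = [(start, end)]
    if introns is None:
        introns = [(cds[i][1] + 1, cds[i + 1][0] - 1)
                   for i in range(len(cds) - 1)]
    if promoter is None:
        promoter = (start - 2000, start - 1) if strand == "+" \
            else (end + 1, end + 2000)
    return GeneModel(gene_id=gene_id, chrom=chrom, strand=strand,
                     start=start, end=end, cds=cds, introns=introns,
                     promoter=promoter)


def brute_force_overlaps(svs, genes):
    """O(n*m) closed-interval oracle mirroring the category definitions."""
    out = {}
    for sv in svs:
        if sv.svtype == "INS":
            pieces = [(sv.chrom, sv.start, sv.start)]
        elif sv.svtype == "BND":
            pieces = [(sv.chrom, sv.start, sv.start)]
            if sv.mate_chrom:
                pieces.append((sv.mate_chrom, sv.mate_pos, sv.mate_pos))
        else:
            pieces = [(sv.chrom, sv.start, sv.end)]
        for g in genes:
            for category, ivs in (("CDS", g.cds), ("intron", g.introns),
                                  ("promoter", [g.promoter] if g.promoter else [])):
                for s, e in ivs:
                    for chrom, a, b in pieces:
                        if chrom != g.chrom:
                            continue
                        ov = min(b, e) - max(a, s) + 1
                        if ov >= 1:
                            key = (sv.event_id, g.gene_id, category)
                            out[key] = out.get(key, 0) + ov
    return out


class TestOverlaps:
    def test_cds_overlap_arithmetic(self):
        sv = make_sv(id="d1", start=10_100, end=10_400, event_id="d1")
        sv.event_id = "d1"
        (call,) = sv_gene_overlaps([sv], [gene(cds=[(10_000, 10_500)],
                                               end=10_500)])
        assert (call.category, call.overlap_bp) == ("CDS", 301)

    def test_promoter_only_hit(self):
        sv = make_sv(id="d2", start=8_500, end=9_500, event_id="d2")
        calls = sv_gene_overlaps([sv], [gene()])
        assert [c.category for c in calls] == ["promoter"]

    def test_other_chromosome_no_calls(self):
        sv = make_sv(id="d3", chrom="contig9", event_id="d3")
        assert sv_gene_overlaps([sv], [gene()]) == []

    def test_insertion_is_a_point(self):
        inside = make_sv(id="i1", svtype="INS", start=10_050, end=10_050,
                         svlen=700, event_id="i1")
        calls = sv_gene_overlaps([inside], [gene(cds=[(10_000, 10_100)],
                                                 end=10_100)])
        assert [(c.category, c.overlap_bp) for c in calls] == [("CDS", 1)]

    def test_bnd_contributes_both_breakpoints(self):
        sv = make_sv(id="b1", svtype="BND", start=10_050, end=10_050, svlen=0,
                     mate_id="m", mate_chrom="contig2", mate_pos=5_000,
                     event_id="b1")
        genes = [gene(gene_id="gA"),
                 gene(gene_id="gB", chrom="contig2", start=4_900, end=6_000,
                      cds=[(4_900, 6_000)])]
        calls = sv_gene_overlaps([sv], genes)
        assert {(c.gene_id, c.category) for c in calls} == \
               {("gA", "CDS"), ("gB", "CDS")}

    def test_whole_gene_spanning_del_counts_as_cds(self):
        sv = make_sv(id="big", start=5_000, end=20_000, svlen=15_000,
                     event_id="big")
        calls = sv_gene_overlaps([sv], [gene()])
        assert "CDS" in {c.category for c in calls}

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        genes = []
        for k in range(30):
            start = int(rng.integers(3_000, 400_000))
            n_cds = int(rng.integers(1, 4))
            bounds = np.sort(rng.choice(np.arange(start, start + 4_000),
                                        size=2 * n_cds, replace=False))
            cds = [(int(bounds[2 * i]), int(bounds[2 * i + 1]))
                   for i in range(n_cds)]
            genes.append(gene(gene_id=f"g{k}", start=cds[0][0],
                              end=cds[-1][1], cds=cds))
        svs = []
        for k in range(100):
            start = int(rng.integers(1, 400_000))
            svtype = ["DEL", "INS", "DUP"][int(rng.integers(3))]
            end = start if svtype == "INS" else start + int(rng.integers(50, 8_000))
            sv = make_sv(id=f"s{k}", svtype=svtype, start=start, end=end,
                         strands="+-" if svtype != "DUP" else "-+",
                         svlen=max(1, end - start), event_id=f"s{k}")
            svs.append(sv)
        got = {(c.event_id, c.gene_id, c.category): c.overlap_bp
               for c in sv_gene_overlaps(svs, genes)}
        assert got == brute_force_overlaps(svs, genes)


class TestGeneLevelSummary:
    def test_precedence_cds_over_promoter(self):
        g = [gene()]
        svs = [make_sv(id="p", start=8_500, end=9_500, event_id="p"),
               make_sv(id="c", start=10_100, end=10_200, event_id="c")]
        calls = sv_gene_overlaps(svs, g)
        per_gene, counts = gene_level_summary(calls, g)
        assert per_gene == {"g1": "CDS"}
        assert counts["CDS"] == 1 and counts["promoter"] == 0

    def test_partition_identities(self):
        genes = [gene(gene_id=f"g{k}", start=10_000 + 30_000 * k,
                      end=12_000 + 30_000 * k,
                      cds=[(10_000 + 30_000 * k, 12_000 + 30_000 * k)])
                 for k in range(10)]
        svs = [make_sv(id=f"s{k}", start=9_000 + 30_000 * k,
                       end=10_500 + 30_000 * k, event_id=f"s{k}")
               for k in range(4)]
        calls = sv_gene_overlaps(svs, genes)
        _, counts = gene_level_summary(calls, genes)
        assert counts["affected"] + counts["unaffected"] == counts["total"]
        assert counts["CDS"] + counts["intron"] + counts["promoter"] \
            == counts["affected"]

    def test_no_svs(self):
        _, counts = gene_level_summary([], [gene()])
        assert counts["affected"] == 0 and counts["unaffected"] == 1

    def test_affected_gene_table_shape(self):
        g = [gene()]
        svs = [make_sv(id="c", start=10_100, end=10_200, event_id="c")]
        table = affected_gene_table(sv_gene_overlaps(svs, g))
        assert list(table.columns) == ["gene_id", "category", "n_svs", "sv_ids"]
        assert table.iloc[0]["sv_ids"] == "c"
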
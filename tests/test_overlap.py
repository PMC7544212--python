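"""Overlap typology, the 2-kb downstream-PAS statistic and read-through calls."""

import pytest

from tifseq2.assembly import TIF
from tifseq2.clustering import ConsensusCluster
from tifseq2.io import GeneModel
from tifseq2.overlap import (OverlapRecord, classify_pattern,
                             detect_read_through, pairwise_overlap,
                             tandem_pas_statistic)


def span_tif(tid, left, right, strand="+", chrom="chr1"):
    """TIF with 1-bp clusters at the span ends (TSS at the 5' end)."""
    tss, pas = (left, right - 1) if strand == "+" else (right - 1, left)

    def clus(kind, pos):
        return ConsensusCluster(id=f"{tid}.{kind}", chrom=chrom, strand=strand,
                                kind=kind, start=pos, end=pos + 1,
                                dominant_pos=pos)
    return TIF(id=tid, chrom=chrom, strand=strand,
               tss_cluster=clus("TSS", tss), pas_cluster=clus("PAS", pas),
               support={"s1": 5})


class TestPairwiseOverlap:
    def test_partial_overlap_arithmetic(self):
        recs = pairwise_overlap([span_tif("A", 0, 1000), span_tif("B", 500, 2000)])
        (r,) = recs
        assert r.overlap_width == 500
        assert r.frac_a == pytest.approx(0.5)
        assert r.frac_b == pytest.approx(1 / 3)
        assert r.signed_offset == 500

    def test_identical_spans_fully_overlap(self):
        recs = pairwise_overlap([span_tif("A", 0, 1000), span_tif("B", 0, 1000)])
        (r,) = recs
        assert r.frac_a == r.frac_b == 1.0

    def test_disjoint_pair_reports_gap(self):
        recs = pairwise_overlap([span_tif("A", 0, 100), span_tif("B", 300, 400)])
        (r,) = recs
        assert r.overlap_width == 0 and r.gap == 200
        assert r.signed_offset == -200

    def test_window_limits_pairing(self):
        recs = pairwise_overlap([span_tif("A", 0, 100),
                                 span_tif("B", 50_000, 50_100)])
        assert recs == []

    def test_upstream_ordering_is_strand_aware(self):
        recs = pairwise_overlap([span_tif("A", 0, 1000, strand="-"),
                                 span_tif("B", 500, 2000, strand="-")])
        (r,) = recs
        assert r.tif_a.id == "B"  # larger TSS is upstream on the minus strand


class TestClassifyPattern:
    def rec(self, frac_a, frac_b, overlap=100):
        a, b = span_tif("A", 0, 1000), span_tif("B", 0, 1000)
        return OverlapRecord(a, b, overlap, 0, frac_a, frac_b, 100)

    @pytest.mark.parametrize("fa, fb, pattern", [
        (0.95, 0.97, "high_overlap"),
        (0.95, 0.30, "truncated"),
        (0.10, 0.15, "low_tandem"),
        (0.5, 0.5, "other"),
    ])
    def test_rule_table(self, fa, fb, pattern):
        assert classify_pattern(self.rec(fa, fb)) == pattern

    def test_disjoint(self):
        r = self.rec(0.0, 0.0, overlap=0)
        assert classify_pattern(r) == "disjoint"

    def test_symmetric_for_high_overlap_and_low_tandem(self):
        for fa, fb in [(0.95, 0.97), (0.10, 0.15)]:
            assert classify_pattern(self.rec(fa, fb)) == \
                classify_pattern(self.rec(fb, fa))

    def test_patterns_partition_all_records(self, default_sim):
        recs = default_sim["result"].overlaps
        assert all(r.pattern in ("high_overlap", "truncated", "low_tandem",
                                 "other", "disjoint") for r in recs)

    def test_designed_layout_fractions_classify_exactly(self):
        """Spans engineered to the designed overlap fractions classify as
        high_overlap / truncated / low_tandem with no ambiguity."""
        layouts = {
            "high_overlap": [(0, 1000), (30, 1000)],     # 0.97 / 1.0 of 970
            "truncated": [(0, 1000), (700, 1016)],       # 0.30 vs 0.95 of 316
            "low_tandem": [(0, 3000), (2700, 4700)],     # 0.10 / 0.15
        }
        for want, ((a0, a1), (b0, b1)) in layouts.items():
            recs = pairwise_overlap([span_tif("A", a0, a1),
                                     span_tif("B", b0, b1)])
            assert recs[0].pattern == want, (want, recs[0])


class TestTandemPasStatistic:
    def tandem(self, pas_offset):
        """Upstream TIF ending ``pas_offset`` bp past the downstream TSS."""
        a = span_tif("A", 0, 3000 + pas_offset)
        b = span_tif("B", 3000, 9000)
        return pairwise_overlap([a, b])

    def test_within_two_kb_counted(self):
        frac, flags = tandem_pas_statistic(self.tandem(1500))
        assert frac == 1.0

    def test_beyond_two_kb_not_counted(self):
        frac, flags = tandem_pas_statistic(self.tandem(2500))
        assert frac == 0.0

    def test_empty_input_reports_absent(self):
        frac, flags = tandem_pas_statistic([])
        assert frac is None and flags == []

    def test_simulated_tandem_layouts_all_within_window(self, tmp_path):
        """A layout of only tandem pairs plants every upstream PAS <=2 kb
        into the downstream unit, so the statistic is exactly 1."""
        from tifseq2.pipeline import run_pipeline
        from tifseq2.simulate import SimConfig
        from conftest import write_sim

        cfg = SimConfig(seed=17, jitter_sd=0.0, pcr_dup_rate=0.0,
                        priming_rate=0.0, chimera_rate=0.0,
                        n_isolated=0, n_multi=0, n_readthrough_pairs=0,
                        n_unannotated=0, n_tandem_pairs=4)
        rc, truth = write_sim(cfg, tmp_path)
        res = run_pipeline(rc, write_outputs=False)
        frac, flags = tandem_pas_statistic(res.overlaps)
        assert frac == 1.0 and len(flags) == 4


class TestReadThrough:
    GENES = [GeneModel("A", "chr1", "+", 1000, 2000),
             GeneModel("B", "chr1", "+", 3000, 4000),
             GeneModel("C", "chr2", "+", 1000, 2000)]

    def test_bridging_tif_called(self):
        tif = span_tif("T", 1200, 3800)
        (call,) = detect_read_through([tif], self.GENES)
        assert (call.upstream_gene, call.downstream_gene) == ("A", "B")
        assert call.tss_location == "inside" and call.pas_location == "inside"

    def test_tif_inside_one_gene_not_called(self):
        assert detect_read_through([span_tif("T", 1100, 1900)], self.GENES) == []

    def test_intergenic_tss_not_called(self):
        # TSS 500 bp upstream of gene A: beyond tolerance, no upstream gene
        assert detect_read_through([span_tif("T", 500, 3800)], self.GENES) == []

    def test_near_tolerance_allows_call(self):
        calls = detect_read_through([span_tif("T", 900, 3800)], self.GENES)
        assert calls and calls[0].tss_location == "near"

    def test_overlapping_genes_excluded_from_candidacy(self):
        genes = self.GENES + [GeneModel("B2", "chr1", "+", 3500, 4500)]
        assert detect_read_through([span_tif("T", 1200, 3800)], genes) == []

    def test_skipped_gene_disqualifies_unless_allowed(self):
        genes = [GeneModel("A", "chr1", "+", 1000, 2000),
                 GeneModel("M", "chr1", "+", 2200, 2800),
                 GeneModel("B", "chr1", "+", 3000, 4000)]
        tif = span_tif("T", 1200, 3800)
        assert detect_read_through([tif], genes) == []
        calls = detect_read_through([tif], genes, allow_skipped_genes=True)
        assert len(calls) == 1

    def test_minus_strand_downstream_ordering(self):
        genes = [GeneModel("A", "chr1", "-", 3000, 4000),
                 GeneModel("B", "chr1", "-", 1000, 2000)]
        tif = span_tif("T", 1200, 3800, strand="-")  # TSS right, PAS left
        (call,) = detect_read_through([tif], genes)
        assert (call.upstream_gene, call.downstream_gene) == ("A", "B")

    def test_simulated_fusions_recovered_exactly(self, noiseless_sim):
        """On fusion layouts without jitter, read-through calls match the
        planted fusion isoforms one-to-one."""
        res = noiseless_sim["result"]
        truth = noiseless_sim["truth"]
        fusions = truth.isoforms[truth.isoforms["kind"] == "fusion"]
        calls = res.read_through
        assert len(calls) == len(fusions)
        called_pairs = {(c.upstream_gene, c.downstream_gene) for c in calls}
        tr_by_id = {}
        for iso in truth.isoforms.itertuples():
            tr_by_id[iso.iso_id] = iso
        want_pairs = set()
        for f in fusions.itertuples():
            up, down = f.iso_id.replace(".fusion", "").split("-")
            want_pairs.add((up, down))
        assert called_pairs == want_pairs

    def test_no_calls_without_fusion_layouts(self, tmp_path):
        """A simulation containing no read-through pairs yields zero calls."""
        from tifseq2.pipeline import run_pipeline
        from tifseq2.simulate import SimConfig
        from conftest import write_sim

        cfg = SimConfig(seed=13, jitter_sd=0.0, pcr_dup_rate=0.0,
                        priming_rate=0.0, chimera_rate=0.0,
                        n_readthrough_pairs=0, n_isolated=10, n_multi=4)
        rc, truth = write_sim(cfg, tmp_path)
        res = run_pipeline(rc, write_outputs=False)
        assert res.read_through == []
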
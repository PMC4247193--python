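import pytest

from drnatss import classify, utrs
from drnatss.config import ClassificationParams, UtrParams
from drnatss.detect import TSSCandidate
from drnatss.io import Feature, GenomeAnnotation

UP = UtrParams()
CP = ClassificationParams()


def gene(start1, end1, strand="+", tag="g1"):
    return Feature(tag, "chr", start1 - 1, end1, strand)


class TestUtrLength:
    def test_basic_distance(self):
        assert utrs.utr_length(980, "+", gene(1001, 2000)) == 20

    def test_coincident_is_zero(self):
        assert utrs.utr_length(1000, "+", gene(1001, 2000)) == 0

    def test_leaderless_boundary_eight(self):
        assert utrs.utr_length(992, "+", gene(1001, 2000)) == 8

    def test_reverse_strand(self):
        assert utrs.utr_length(2019, "-", gene(1001, 2000, "-")) == 20

    def test_downstream_tss_is_error(self):
        with pytest.raises(ValueError, match="downstream"):
            utrs.utr_length(1500, "+", gene(1001, 2000))


class TestClassifyUtrs:
    def _rec(self, length):
        return utrs.UTRRecord("g", 0, "pTSS", length, length <= 8,
                              50 <= length <= 300, 40.0)

    def test_median(self):
        s = utrs.classify_utrs([self._rec(x) for x in (0, 16, 40)])
        assert s.median == 16

    def test_all_leaderless(self):
        s = utrs.classify_utrs([self._rec(x) for x in (0, 3, 8)])
        assert s.leaderless_fraction == 1.0

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            utrs.classify_utrs([])

    def test_flags_consistent_with_length(self, sim900):
        _params, res = sim900
        for r in res.utr_records:
            assert r.utr_length >= 0
            assert r.leaderless == (r.utr_length <= 8)
            assert r.long_utr == (50 <= r.utr_length <= 300)
            assert not (r.leaderless and r.long_utr)


def _misannotated_genome():
    """GTG-start gene whose true ATG sits 3 codons downstream, with an RBS
    planted upstream of the ATG; the TSS leaves a 3 nt annotated 5'-UTR."""
    left = "T" * 100
    rbs_region = "AAGGAGGA"          # GGAGGA hexamer, ends 11 nt before ATG
    gap = "TCA"
    utr3 = "CAC"
    coding = "GTG" + "CAA" + "CAC" + "ATG" + "CCACTTCAT" * 12 + "TAA"
    seq = left + rbs_region + gap + utr3 + coding + "T" * 100
    gstart = len(left + rbs_region + gap + utr3)
    g = Feature("g1", "chr", gstart, gstart + len(coding), "+")
    ann = GenomeAnnotation(sequences={"chr": seq}, features=[g])
    tss = gstart - 3
    return ann, g, tss


class TestReassignment:
    def test_planted_gtg_to_atg(self):
        ann, g, tss = _misannotated_genome()
        cand = TSSCandidate("chr", tss, "+", heights={"l": 40.0})
        recs = classify.classify_all([cand], ann, CP)
        r = utrs.reassign_start_codon(g, recs[0], ann, UP)
        assert r is not None
        assert r.new_codon == "ATG" and r.frame_offset_codons == 3
        assert r.new_start_pos == g.start + 9
        assert r.rbs_found and r.old_utr == 3 and r.new_utr == 12

    def test_no_alternative_start_returns_none(self):
        ann, g, tss = _misannotated_genome()
        # overwrite the ATG with a scrubbed codon
        s = ann.sequences["chr"]
        ann.sequences["chr"] = s[:g.start + 9] + "CCA" + s[g.start + 12:]
        cand = TSSCandidate("chr", tss, "+", heights={"l": 40.0})
        recs = classify.classify_all([cand], ann, CP)
        assert utrs.reassign_start_codon(g, recs[0], ann, UP) is None

    def test_internal_tss_recategorized_to_primary(self):
        """An iTSS near a gene's 5' end plus a downstream in-frame ATG+RBS
        moves the start codon and turns the iTSS into the gene's pTSS."""
        left = "T" * 60
        coding_head = "ATG" + "CAACAC" * 5       # annotated start + 10 codons
        rbs = "AAGGAGGA" + "TCAT"                # in-frame pad; RBS 4 nt before ATG
        coding_tail = "ATG" + "CCACTTCAT" * 10 + "TAA"
        seq = left + coding_head + rbs + coding_tail + "T" * 60
        gstart = len(left)
        gend = len(left + coding_head + rbs + coding_tail)
        g = Feature("g1", "chr", gstart, gend, "+")
        ann = GenomeAnnotation(sequences={"chr": seq}, features=[g])
        itss_pos = gstart + 30                    # 30 nt into the gene
        cand = TSSCandidate("chr", itss_pos, "+", heights={"l": 40.0})
        recs = classify.classify_all([cand], ann, CP)
        assert recs[0].classes() == {"iTSS"}
        found = utrs.screen_reassignments(recs, ann, UP)
        assert len(found) == 1 and found[0].rbs_found
        new_recs, new_utrs, updated, changes = utrs.recategorize(
            recs, found, ann, CP, UP)
        assert new_recs[0].classes() == {"pTSS"}
        assert len(changes) == 1

    def test_recategorize_clears_leaderless(self):
        ann, g, tss = _misannotated_genome()
        cand = TSSCandidate("chr", tss, "+", heights={"l": 40.0})
        recs = classify.classify_all([cand], ann, CP)
        before = utrs.build_utr_records(recs, ann, UP)
        assert before[0].leaderless
        found = utrs.screen_reassignments(recs, ann, UP)
        _new_recs, after, _ann2, _ = utrs.recategorize(recs, found, ann, CP, UP)
        assert len(found) == 1
        assert not after[0].leaderless and after[0].utr_length == 12

    def test_empty_reassignment_set_is_identity(self, sim200, cfg):
        _params, res = sim200
        recs, new_utrs, updated, changes = utrs.recategorize(
            res.records, [], res.annotation, cfg.classification, cfg.utr)
        assert changes == []
        assert updated.features == res.annotation.features
        got = {(r.candidate.position, r.candidate.strand):
               frozenset(r.assignments) for r in recs}
        want = {(r.candidate.position, r.candidate.strand):
                frozenset(r.assignments) for r in res.records}
        assert got == want

    def test_idempotence_on_synthetic_data(self, sim900, cfg):
        """A second screening round after applying the first one finds no
        further reassignments (single planted alternative starts)."""
        _params, res = sim900
        second = utrs.screen_reassignments(res.records, res.annotation,
                                           cfg.utr)
        assert second == []

    def test_never_shortens_utr_or_leaves_frame(self, sim900):
        _params, res = sim900
        idx = res.original_annotation.feature_index
        for r in res.reassignments:
            g = idx[r.locus_tag]
            shift = (r.new_start_pos - r.old_start_pos if g.strand == "+"
                     else r.old_start_pos - r.new_start_pos)
            assert shift > 0 and shift % 3 == 0
            if r.old_utr is not None and r.new_utr is not None:
                assert r.new_utr > r.old_utr
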
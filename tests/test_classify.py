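import numpy as np
import pytest

from drnatss import classify
from drnatss.config import ClassificationParams
from drnatss.detect import TSSCandidate
from drnatss.io import Feature, GenomeAnnotation
from oracles import naive_classify, naive_primary_secondary

PARAMS = ClassificationParams()


def ann_with(*genes):
    return GenomeAnnotation(
        sequences={"chr": "A" * 5000},
        features=[Feature(tag, "chr", s, e, strand) for tag, s, e, strand in genes])


def cand(pos1, strand, height=10.0):
    """1-based position for readability against the geometric examples."""
    return TSSCandidate("chr", pos1 - 1, strand, heights={"lib": height})


GENE = ("g1", 1000, 2000, "+")  # 1-based 1001..2000


class TestGeometry:
    def test_upstream_within_300(self):
        out = classify.classify_tss(cand(951, "+"), ann_with(GENE), PARAMS)
        assert out == {("upstream", "g1")}

    def test_antisense_inside_gene(self):
        out = classify.classify_tss(cand(1500, "-"), ann_with(GENE), PARAMS)
        assert out == {("aTSS", "g1")}

    def test_antisense_flank_boundary_inclusive(self):
        assert classify.classify_tss(cand(2100, "-"), ann_with(GENE),
                                     PARAMS) == {("aTSS", "g1")}
        assert classify.classify_tss(cand(2101, "-"), ann_with(GENE),
                                     PARAMS) == {("oTSS", None)}

    def test_orphan_beyond_300(self):
        out = classify.classify_tss(cand(650, "+"), ann_with(GENE), PARAMS)
        assert out == {("oTSS", None)}

    def test_at_start_codon_counts_as_upstream(self):
        out = classify.classify_tss(cand(1001, "+"), ann_with(GENE), PARAMS)
        assert out == {("upstream", "g1")}

    def test_internal(self):
        out = classify.classify_tss(cand(1500, "+"), ann_with(GENE), PARAMS)
        assert out == {("iTSS", "g1")}

    def test_internal_and_upstream_of_downstream_gene(self):
        ann = ann_with(("gA", 1000, 2000, "+"), ("gB", 2100, 3000, "+"))
        out = classify.classify_tss(cand(1900, "+"), ann, PARAMS)
        assert out == {("iTSS", "gA"), ("upstream", "gB")}


class TestPrimarySecondary:
    def _records(self, heights, strand="+"):
        ann = ann_with(GENE)
        cands = [cand(900 + 10 * i, strand, h) for i, h in enumerate(heights)]
        return classify.classify_all(cands, ann, PARAMS)

    def test_maximum_height_wins(self):
        recs = self._records([30.0, 100.0, 60.0])
        labels = [next(iter(r.classes())) for r in recs]
        assert labels == ["sTSS", "pTSS", "sTSS"]

    def test_tie_breaks_upstream(self):
        recs = self._records([100.0, 100.0])
        assert [next(iter(r.classes())) for r in recs] == ["pTSS", "sTSS"]

    def test_single_upstream_is_primary(self):
        recs = self._records([40.0])
        assert recs[0].classes() == {"pTSS"}

    def test_at_most_one_primary_per_gene(self, sim900):
        _params, res = sim900
        per_gene = {}
        for r in res.records:
            for cls, tag in r.assignments:
                if cls == "pTSS":
                    per_gene[tag] = per_gene.get(tag, 0) + 1
        assert per_gene and all(v == 1 for v in per_gene.values())


class TestSummary:
    def test_counts_and_overlap(self):
        ann = ann_with(("gA", 1000, 2000, "+"), ("gB", 2100, 3000, "+"))
        recs = classify.classify_all(
            [cand(1900, "+"), cand(500, "-")], ann, PARAMS)
        s = classify.category_summary(recs)
        assert s["unique_tss"] == 2
        assert s["total_assignments"] == 3  # iTSS+pTSS and one oTSS
        assert s["per_class"]["iTSS"] == 1 and s["per_class"]["pTSS"] == 1
        assert s["overlap"][("iTSS", "pTSS")] == 1

    def test_exhaustive_and_orphan_exclusive(self, sim200):
        _params, res = sim200
        for r in res.records:
            assert r.assignments
            if "oTSS" in r.classes():
                assert len(r.assignments) == 1


class TestTerminusEnrichment:
    def test_at_stop_codon_is_three_prime(self):
        ann = ann_with(GENE)
        recs = classify.classify_all([cand(2000, "-")], ann, PARAMS)
        out = classify.terminus_enrichment(recs, ann, 150)
        assert out["near_3prime"] == 1 and out["near_5prime"] == 0

    def test_midpoint_of_1kb_gene_is_neither(self):
        ann = ann_with(GENE)
        recs = classify.classify_all([cand(1500, "-")], ann, PARAMS)
        out = classify.terminus_enrichment(recs, ann, 150)
        assert out["near_5prime"] == 0 and out["near_3prime"] == 0
        assert out["near_any_fraction"] == 0.0


class TestBruteForceEquivalence:
    def test_random_layouts(self):
        """Module classifier equals the nested-loop oracle on random gene
        layouts, including overlapping genes and multi-class TSS."""
        rng = np.random.default_rng(12)
        for _ in range(100):
            genes = []
            for gi in range(rng.integers(2, 10)):
                s = int(rng.integers(0, 4000))
                e = s + int(rng.integers(50, 900))
                genes.append((f"g{gi}", s, min(e, 4999),
                              "+" if rng.random() < 0.5 else "-"))
            ann = ann_with(*genes)
            tss = [(int(rng.integers(0, 4999)),
                    "+" if rng.random() < 0.5 else "-",
                    float(rng.integers(1, 100)))
                   for _ in range(rng.integers(5, 25))]
            cands = [TSSCandidate("chr", p, s, heights={"lib": h})
                     for p, s, h in tss]
            recs = classify.classify_all(cands, ann, PARAMS)
            expected = naive_primary_secondary(tss, genes)
            for rec, exp in zip(recs, expected):
                assert rec.assignments == exp, (rec.candidate.position,
                                                rec.candidate.strand)
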
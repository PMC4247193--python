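import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from drnatss import detect
from drnatss.config import DetectionParams
from drnatss.io import CoverageTrack
from oracles import naive_cluster


def track(fwd, rev=None, library_id="lib", condition="c", treated=True):
    n = len(fwd)
    return CoverageTrack(
        library_id, condition, treated,
        counts_fwd={"chr": np.asarray(fwd, dtype=np.int64)},
        counts_rev={"chr": np.asarray(rev if rev is not None else [0] * n,
                                      dtype=np.int64)})


class TestNormalize:
    def test_reads_per_million(self):
        t = track([0] * 9 + [50])
        t.counts_fwd["chr"][0] = 10**6 - 50  # library size exactly 1e6
        h = detect.normalize_track(t, True)
        assert h[("chr", "+")][9] == pytest.approx(50.0)

    def test_off_gives_raw_counts(self):
        h = detect.normalize_track(track([1, 2, 3]), False)
        assert list(h[("chr", "+")]) == [1, 2, 3]

    def test_normalized_sum_is_one_million(self):
        rng = np.random.default_rng(1)
        t = track(rng.poisson(3, 500), rng.poisson(3, 500))
        h = detect.normalize_track(t, True)
        total = sum(a.sum() for a in h.values())
        assert total == pytest.approx(1e6)

    def test_zero_library_size_is_error(self):
        with pytest.raises(ValueError, match="zero library size"):
            detect.normalize_track(track([0, 0]), True)


class TestStepMetrics:
    def test_enrichment_arithmetic(self):
        p = DetectionParams(normalize=False)
        h, step, enr = detect.step_metrics(
            np.array([0.0, 40.0]), np.array([0.0, 8.0]), 1, "+", p)
        assert (h, enr) == (40.0, pytest.approx(40 / 9))

    def test_zero_untreated_capped_by_pseudocount(self):
        p = DetectionParams()
        _, _, enr = detect.step_metrics(
            np.array([0.0, 40.0]), np.zeros(2), 1, "+", p)
        assert enr == pytest.approx(40.0)

    def test_zero_upstream_uses_pseudocount(self):
        p = DetectionParams()
        _, step, _ = detect.step_metrics(
            np.array([0.0, 40.0]), np.zeros(2), 1, "+", p)
        assert step == pytest.approx(40.0)

    def test_reverse_strand_upstream_is_right_neighbour(self):
        p = DetectionParams()
        _, step, _ = detect.step_metrics(
            np.array([0.0, 40.0, 20.0]), np.zeros(3), 1, "-", p)
        assert step == pytest.approx(2.0)


class TestCallCandidates:
    P = DetectionParams(normalize=False)

    def test_single_planted_peak(self):
        fwd_t, fwd_u = [0] * 50, [0] * 50
        fwd_t[20], fwd_u[20] = 40, 2
        out = detect.call_candidates(track(fwd_t), track(fwd_u, treated=False),
                                     self.P)
        assert [(c.position, c.strand) for c in out] == [(20, "+")]
        assert out[0].enrichment_factor == pytest.approx(40 / 3)

    def test_flat_track_yields_nothing(self):
        out = detect.call_candidates(track([10] * 50),
                                     track([0] * 50, treated=False), self.P)
        assert out == []  # step factor is 1 everywhere

    def test_unenriched_peak_yields_nothing(self):
        fwd = [0] * 50
        fwd[20] = 40
        out = detect.call_candidates(track(fwd), track(fwd, treated=False),
                                     self.P)
        assert out == []  # enrichment 40/41 < 2

    def test_mismatched_layout_is_error(self):
        with pytest.raises(ValueError, match="mismatched"):
            detect.call_candidates(track([0] * 10), track([0] * 20,
                                                          treated=False), self.P)


def cand(pos, height, strand="+"):
    return detect.TSSCandidate(replicon="chr", position=pos, strand=strand,
                               heights={"lib": float(height)})


class TestCluster:
    def test_representative_is_maximum(self):
        out = detect.cluster_candidates(
            [cand(100, 10), cand(101, 50), cand(103, 7)], 3)
        assert [(c.position, c.total_height) for c in out] == [(101, 50.0)]

    def test_tie_breaks_upstream(self):
        out = detect.cluster_candidates([cand(100, 5), cand(101, 5)], 3)
        assert out[0].position == 100
        out = detect.cluster_candidates(
            [cand(100, 5, "-"), cand(101, 5, "-")], 3)
        assert out[0].position == 101  # upstream on − is the larger coordinate

    @settings(max_examples=100, deadline=None)
    @given(positions=st.lists(st.integers(0, 300), min_size=1, max_size=30,
                              unique=True),
           window=st.integers(1, 5))
    def test_partition_matches_single_linkage_oracle(self, positions, window):
        cands = [cand(p, h) for h, p in enumerate(sorted(positions))]
        out = detect.cluster_candidates(cands, window)
        expected = naive_cluster(positions, window)
        reps = sorted(c.position for c in out)
        assert len(reps) == len(expected)
        for rep, part in zip(reps, expected):
            assert rep in part


class TestMerge:
    def test_same_position_across_four_conditions(self):
        lists = [[detect.TSSCandidate("chr", 500, "+", {f"c{i}": 10.0},
                                      detected_in=frozenset({f"c{i}"}))]
                 for i in range(4)]
        out = detect.merge_libraries(lists, 1)
        assert len(out) == 1 and len(out[0].detected_in) == 4

    def test_adjacent_positions_unify(self):
        lists = [[detect.TSSCandidate("chr", 500, "+", {"a": 10.0},
                                      detected_in=frozenset({"a"}))],
                 [detect.TSSCandidate("chr", 501, "+", {"b": 30.0},
                                      detected_in=frozenset({"b"}))]]
        out = detect.merge_libraries(lists, 1)
        assert len(out) == 1 and out[0].position == 501  # higher summed height

    def test_disjoint_sets_union(self):
        lists = [[cand(100, 5)], [cand(500, 5)], [cand(900, 5)]]
        assert len(detect.merge_libraries(lists, 1)) == 3


class TestOnSyntheticData:
    def test_thresholds_hold_post_hoc(self, sim200, cfg):
        """Every reported TSS satisfies all three thresholds in at least one
        treated library, re-checked directly against the tracks."""
        _params, res = sim200
        p = cfg.detection
        heights = {cond: detect.normalize_track(res.tracks[(cond, True)],
                                                p.normalize)
                   for cond, tr in [(c, t) for (c, t) in res.tracks if t]}
        unheights = {cond: detect.normalize_track(res.tracks[(cond, False)],
                                                  p.normalize)
                     for cond, tr in [(c, t) for (c, t) in res.tracks if t]}
        for c in res.candidates:
            ok = False
            for cond in heights:
                h, step, enr = detect.step_metrics(
                    heights[cond][(c.replicon, c.strand)],
                    unheights[cond][(c.replicon, c.strand)],
                    c.position, c.strand, p)
                if (h >= p.min_height and step >= p.min_step_factor
                        and enr >= p.min_enrichment):
                    ok = True
                    break
            # the representative may sit ±1 from the thresholded position
            # after clustering; accept if a cluster member passes
            if not ok:
                for d in (-1, 1):
                    for cond in heights:
                        h, step, enr = detect.step_metrics(
                            heights[cond][(c.replicon, c.strand)],
                            unheights[cond][(c.replicon, c.strand)],
                            c.position + d, c.strand, p)
                        if (h >= p.min_height and step >= p.min_step_factor
                                and enr >= p.min_enrichment):
                            ok = True
            assert ok, (c.position, c.strand)

    def test_threshold_monotonicity(self, sim200, cfg):
        """Raising any threshold never increases the number of called TSS."""
        _params, res = sim200
        base = cfg.detection
        n_base = len(detect.detect_tss(res.tracks, base))
        import dataclasses
        for field, factor in (("min_height", 2.0), ("min_step_factor", 2.0),
                              ("min_enrichment", 2.0)):
            tighter = dataclasses.replace(base,
                                          **{field: getattr(base, field) * factor})
            assert len(detect.detect_tss(res.tracks, tighter)) <= n_base
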
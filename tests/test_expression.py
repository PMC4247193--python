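import numpy as np
import pandas as pd
import pytest

from drnatss import expression as ex
from drnatss.config import ExpressionParams
from drnatss.io import CoverageTrack, Feature, GenomeAnnotation


def make_track(fwd, library_id="lib"):
    n = len(fwd)
    return CoverageTrack(library_id, "c", False,
                         counts_fwd={"chr": np.asarray(fwd, dtype=np.int64)},
                         counts_rev={"chr": np.zeros(n, dtype=np.int64)})


class TestGeneCounts:
    def test_per_kb_average(self):
        ann = GenomeAnnotation(sequences={"chr": "A" * 2000},
                               features=[Feature("g1", "chr", 0, 1000, "+")])
        fwd = np.zeros(2000, int)
        fwd[100:600] = 1  # 500 reads inside the gene
        assert ex.gene_counts(make_track(fwd), ann)["g1"] == pytest.approx(500.0)

    def test_zero_coverage(self):
        ann = GenomeAnnotation(sequences={"chr": "A" * 100},
                               features=[Feature("g1", "chr", 0, 60, "+")])
        assert ex.gene_counts(make_track([0] * 100), ann)["g1"] == 0.0

    def test_overlapping_genes_count_twice(self):
        ann = GenomeAnnotation(
            sequences={"chr": "A" * 300},
            features=[Feature("g1", "chr", 0, 200, "+"),
                      Feature("g2", "chr", 100, 300, "+")])
        fwd = np.zeros(300, int)
        fwd[150] = 10  # inside both genes
        s = ex.gene_counts(make_track(fwd), ann)
        assert s["g1"] == pytest.approx(50.0) and s["g2"] == pytest.approx(50.0)


class TestSizeFactors:
    def test_doubled_library(self):
        rng = np.random.default_rng(2)
        a = pd.Series(rng.integers(5, 100, 50).astype(float))
        mat = pd.DataFrame({"A": a, "B": 2.0 * a})
        f = ex.size_factors(mat)
        assert f["B"] / f["A"] == pytest.approx(2.0, abs=1e-9)
        norm = ex.normalize(mat)
        assert np.allclose(norm["A"], norm["B"])

    def test_duplicated_library_gives_unit_factors(self):
        a = pd.Series([3.0, 10.0, 50.0])
        f = ex.size_factors(pd.DataFrame({"A": a, "B": a}))
        assert np.allclose(f, 1.0)

    def test_idempotence(self):
        rng = np.random.default_rng(4)
        mat = pd.DataFrame(rng.integers(1, 500, (80, 4)).astype(float),
                           columns=list("abcd"))
        f2 = ex.size_factors(ex.normalize(mat))
        assert np.allclose(f2, 1.0, atol=1e-9)

    def test_matches_direct_formula_on_random_matrices(self):
        from oracles import naive_size_factors
        rng = np.random.default_rng(8)
        for _ in range(100):
            mat = pd.DataFrame(
                rng.integers(0, 60, (rng.integers(5, 30), rng.integers(2, 5))
                             ).astype(float))
            mat.iloc[0] = rng.integers(1, 60, mat.shape[1])  # ensure one all-nonzero
            rows = {i: list(mat.loc[i]) for i in mat.index}
            assert np.allclose(ex.size_factors(mat).values,
                               naive_size_factors(rows))

    def test_all_zero_gene_matrix_is_error(self):
        mat = pd.DataFrame({"A": [0.0, 1.0], "B": [2.0, 0.0]})
        with pytest.raises(ValueError, match="nonzero"):
            ex.size_factors(mat)


class TestTuExpression:
    def test_operon_sum_and_singletons(self):
        mat = pd.DataFrame({"L": {"gA": 10.0, "gB": 30.0, "gC": 7.0}})
        tu = ex.tu_expression(mat, {"op1": ["gA", "gB"]})
        assert tu.loc["op1", "L"] == 40.0 and tu.loc["gC", "L"] == 7.0

    def test_totals_conserved(self, sim900):
        _params, res = sim900
        ann = res.original_annotation
        tracks = [res.tracks[(c, False)] for c in res.truth.conditions]
        mat = ex.count_matrix(tracks, ann)
        tu = ex.tu_expression(mat, ann.operons)
        assert np.allclose(tu.sum().values, mat.sum().values, rtol=1e-12)

    def test_missing_member_is_error(self):
        mat = pd.DataFrame({"L": {"gA": 10.0}})
        with pytest.raises(ValueError, match="missing"):
            ex.tu_expression(mat, {"op1": ["gA", "gZ"]})


class TestBinsAndContrast:
    def test_all_zero_matrix_in_lowest_bin(self):
        tu = pd.DataFrame({"L": [0.0] * 10})
        bins = ex.expression_bins(tu, {}, ExpressionParams())
        assert bins.loc["little_or_none", "L"] == 1.0

    def test_fractions_partition(self):
        rng = np.random.default_rng(1)
        tu = pd.DataFrame({"L": rng.lognormal(3, 2, 200)})
        bins = ex.expression_bins(tu, {}, ExpressionParams())
        assert bins["L"].sum() == pytest.approx(1.0)

    def test_log2_fold_change(self):
        tu = pd.DataFrame({"a": {"t": 400.0}, "b": {"t": 25.0}})
        con = ex.contrast(tu, "a", "b", pseudocount=0.0)
        assert con.loc["t", "log2_fold_change"] == pytest.approx(-4.0)

    def test_equal_libraries_give_zero(self):
        tu = pd.DataFrame({"a": {"t": 7.0}, "b": {"t": 7.0}})
        assert ex.contrast(tu, "a", "b")["log2_fold_change"]["t"] == 0.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(3)
        tu = pd.DataFrame({"a": rng.lognormal(2, 1, 50),
                           "b": rng.lognormal(2, 1, 50)})
        ab = ex.contrast(tu, "a", "b")["log2_fold_change"]
        ba = ex.contrast(tu, "b", "a")["log2_fold_change"]
        assert np.allclose(ab, -ba)

    def test_unknown_library_is_error(self):
        tu = pd.DataFrame({"a": {"t": 1.0}})
        with pytest.raises(KeyError):
            ex.contrast(tu, "a", "zz")


class TestTopExpressed:
    MAT = pd.DataFrame({"L": {"g1": 5.0, "g2": 9.0, "g3": 1.0}})

    def test_ranking(self):
        assert ex.top_expressed(self.MAT, "L", 2) == ["g2", "g1"]

    def test_n_larger_than_gene_count(self):
        assert ex.top_expressed(self.MAT, "L", 10) == ["g2", "g1", "g3"]

    def test_deterministic_tie_break(self):
        mat = pd.DataFrame({"L": {"b": 5.0, "a": 5.0}})
        assert ex.top_expressed(mat, "L", 2) == ["a", "b"]
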
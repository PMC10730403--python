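import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from ironsig import signature_scoring as ss
from ironsig.preprocess import NormalizedMatrix


def _norm(values, genes=None, cells=None):
    values = np.asarray(values, float)
    return NormalizedMatrix(
        values=values,
        gene_ids=genes or [f"g{i}" for i in range(values.shape[0])],
        cell_ids=cells or [f"c{i}" for i in range(values.shape[1])],
        size_factors=np.ones(values.shape[1]),
        scale=1e4,
    )


class TestDiffusionSmoothing:
    def test_t_zero_is_identity(self, rng):
        norm = _norm(rng.normal(size=(10, 30)).clip(min=0))
        out = ss.diffusion_smooth(norm, ss.SmoothingParams(t=0, n_neighbors=5))
        np.testing.assert_array_equal(out.values, norm.values)

    def test_constant_gene_is_fixed_point(self, rng):
        vals = rng.normal(1, 0.5, size=(5, 40)).clip(min=0)
        vals[2] = 0.7
        norm = _norm(vals)
        out = ss.diffusion_smooth(norm, ss.SmoothingParams(t=4, n_neighbors=6, n_pcs=3))
        np.testing.assert_allclose(out.values[2], 0.7, atol=1e-12)

    def test_chain_graph_matches_dense_matrix_power(self):
        """Hand-written 3-cell chain operator: two diffusion steps must equal
        P^2 x by explicit dense multiplication."""
        p = np.array(
            [
                [0.5, 0.5, 0.0],
                [0.25, 0.5, 0.25],
                [0.0, 0.5, 0.5],
            ]
        )
        x = np.array([[1.0, 0.0, 0.0], [2.0, 1.0, 3.0]])
        norm = _norm(x)
        out = ss.diffusion_smooth(
            norm, ss.SmoothingParams(t=2, n_neighbors=1), operator=sp.csr_matrix(p)
        )
        np.testing.assert_allclose(out.values, x @ (p @ p).T)

    def test_operator_rows_sum_to_one(self, rng):
        norm = _norm(rng.normal(size=(20, 50)).clip(min=0))
        op = ss.build_diffusion_operator(
            norm, ss.SmoothingParams(n_neighbors=8, n_pcs=5)
        )
        np.testing.assert_allclose(np.asarray(op.sum(axis=1)).ravel(), 1.0)

    def test_smoothing_preserves_value_range(self, rng):
        norm = _norm(rng.normal(2, 1, size=(8, 60)).clip(min=0))
        out = ss.diffusion_smooth(norm, ss.SmoothingParams(t=3, n_neighbors=10, n_pcs=4))
        for g in range(8):
            assert out.values[g].min() >= norm.values[g].min() - 1e-12
            assert out.values[g].max() <= norm.values[g].max() + 1e-12

    def test_too_few_cells_rejected(self, rng):
        norm = _norm(rng.normal(size=(5, 10)).clip(min=0))
        with pytest.raises(ValueError, match="n_neighbors"):
            ss.diffusion_smooth(norm, ss.SmoothingParams(t=1, n_neighbors=15))


class TestScoreSignature:
    def test_single_gene_signature_equals_gene_value(self):
        norm = _norm([[1.0, 2.0], [5.0, 6.0]], genes=["a", "b"])
        sv = ss.score_signature(norm, ["b"], "one")
        np.testing.assert_allclose(sv.scores, [5.0, 6.0])

    def test_two_gene_average(self):
        norm = _norm([[1.0], [3.0]], genes=["a", "b"])
        sv = ss.score_signature(norm, ["a", "b"])
        assert sv.scores[0] == pytest.approx(2.0)

    def test_gene_order_irrelevant(self, rng):
        norm = _norm(rng.normal(size=(6, 9)), genes=list("abcdef"))
        s1 = ss.score_signature(norm, ["a", "c", "e"])
        s2 = ss.score_signature(norm, ["e", "a", "c"])
        np.testing.assert_array_equal(s1.scores, s2.scores)

    def test_missing_genes_reported(self):
        norm = _norm([[1.0]], genes=["a"])
        sv = ss.score_signature(norm, ["a", "zz"])
        assert sv.missing_genes == ["zz"] and sv.n_genes_used == 1

    def test_all_genes_missing_is_error(self):
        norm = _norm([[1.0]], genes=["a"])
        with pytest.raises(ValueError, match="mysig"):
            ss.score_signature(norm, ["zz"], "mysig")


class TestHighCalls:
    def _scores(self, values, cell_ids):
        return ss.ScoreVector(
            scores=np.asarray(values, float),
            cell_ids=cell_ids,
            signature_name="IAS",
            n_genes_used=1,
            missing_genes=[],
        )

    def test_interpolated_percentile_and_strict_boundary(self, annotation_factory):
        # control scores 0..9 -> interpolated 90th percentile = 8.1
        cells = [f"c{i}" for i in range(12)]
        scores = self._scores(list(range(10)) + [8.2, 8.1], cells)
        annot = annotation_factory(
            cells,
            conditions=["control"] * 10 + ["IPF", "IPF"],
        )
        res = ss.call_signature_high(
            scores, annot, ss.HighCallParams(grouping="global")
        )
        assert res.thresholds["all"] == pytest.approx(8.1)
        assert bool(res.high[10]) is True  # 8.2 > 8.1
        assert bool(res.high[11]) is False  # exactly at threshold

    def test_all_equal_scores_nobody_high(self, annotation_factory):
        cells = [f"c{i}" for i in range(6)]
        scores = self._scores([2.0] * 6, cells)
        annot = annotation_factory(cells, conditions=["control"] * 3 + ["IPF"] * 3)
        res = ss.call_signature_high(scores, annot,
                                     ss.HighCallParams(grouping="global"))
        assert not res.high.any()

    def test_reference_fraction_near_ten_percent(self, annotation_factory, rng):
        n = 500
        cells = [f"c{i}" for i in range(n)]
        scores = self._scores(rng.normal(size=n), cells)
        annot = annotation_factory(cells)  # everything is reference
        res = ss.call_signature_high(scores, annot,
                                     ss.HighCallParams(grouping="global"))
        assert abs(res.high.mean() - 0.10) <= 1.0 / n + 1e-9

    def test_per_cell_type_thresholds_differ(self, annotation_factory, rng):
        cells = [f"c{i}" for i in range(40)]
        vals = np.concatenate([rng.normal(0, 1, 20), rng.normal(10, 1, 20)])
        annot = annotation_factory(cells, cell_types=["A"] * 20 + ["B"] * 20)
        res = ss.call_signature_high(self._scores(vals, cells), annot)
        assert res.thresholds["A"] < res.thresholds["B"]

    def test_stratum_without_reference_marked_missing(self, annotation_factory, caplog):
        cells = ["c0", "c1", "c2", "c3"]
        annot = annotation_factory(
            cells, cell_types=["A", "A", "B", "B"],
            conditions=["control", "IPF", "IPF", "IPF"],
        )
        with caplog.at_level("WARNING"):
            res = ss.call_signature_high(
                self._scores([1, 2, 3, 4], cells), annot
            )
        assert res.missing[2] and res.missing[3]
        assert not res.missing[0]


class TestDoublePositive:
    def _calls(self, high, cells, missing=None):
        n = len(cells)
        return ss.HighCallResult(
            high=np.asarray(high, bool),
            missing=np.asarray(missing if missing is not None else [False] * n),
            thresholds={},
            cell_ids=cells,
            params=ss.HighCallParams(),
        )

    def test_counting(self, annotation_factory):
        cells = ["c0", "c1", "c2"]
        annot = annotation_factory(cells)
        table, _ = ss.tabulate_double_positive(
            self._calls([1, 1, 0], cells), self._calls([1, 0, 0], cells), annot
        )
        assert table["n_cells"].iloc[0] == 3
        assert table["n_double_pos"].iloc[0] == 1

    def test_identical_calls_double_equals_single(self, annotation_factory, rng):
        cells = [f"c{i}" for i in range(30)]
        high = rng.random(30) < 0.4
        annot = annotation_factory(cells)
        table, _ = ss.tabulate_double_positive(
            self._calls(high, cells), self._calls(high, cells), annot
        )
        assert table["n_double_pos"].iloc[0] == high.sum()

    def test_missing_cells_excluded_and_reported(self, annotation_factory):
        cells = ["c0", "c1"]
        annot = annotation_factory(cells)
        table, report = ss.tabulate_double_positive(
            self._calls([1, 1], cells, missing=[False, True]),
            self._calls([1, 1], cells),
            annot,
        )
        assert table["n_cells"].iloc[0] == 1
        assert report["n_cells_excluded_missing"] == 1

    def test_invariant_to_cell_order(self, annotation_factory, rng):
        cells = [f"c{i}" for i in range(20)]
        a = rng.random(20) < 0.5
        b = rng.random(20) < 0.5
        donors = [f"d{i % 3}" for i in range(20)]
        annot = annotation_factory(cells, donors=donors)
        t1, _ = ss.tabulate_double_positive(
            self._calls(a, cells), self._calls(b, cells), annot
        )
        perm = rng.permutation(20)
        cells_p = [cells[i] for i in perm]
        annot_p = annotation_factory(cells_p, donors=[donors[i] for i in perm])
        t2, _ = ss.tabulate_double_positive(
            self._calls(a[perm], cells_p), self._calls(b[perm], cells_p), annot_p
        )
        pd.testing.assert_frame_equal(t1, t2)

    def test_misaligned_inputs_rejected(self, annotation_factory):
        annot = annotation_factory(["c0", "c1"])
        with pytest.raises(ValueError, match="aligned"):
            ss.tabulate_double_positive(
                self._calls([1, 0], ["c0", "c1"]),
                self._calls([1], ["c0"]),
                annot,
            )


class TestPrerankedEnrichment:
    def test_full_set_gives_es_one(self):
        metric = pd.Series([3.0, 2.0, 1.0], index=["a", "b", "c"])
        res = ss.preranked_enrichment(metric, ["a", "b", "c"], n_perm=10, seed=0)
        assert res.es == pytest.approx(1.0)

    def test_hand_computed_running_sum(self):
        # metrics [3,2,1,-1,-2], hits at ranks 1 and 3 (weight 1):
        # NR = 3+1 = 4; miss step = 1/3
        # running: .75, .75-1/3, +1/4 -> .6667, -1/3 -> .3333, -1/3 -> 0
        metric = pd.Series([3.0, 2.0, 1.0, -1.0, -2.0],
                           index=["a", "b", "c", "d", "e"])
        res = ss.preranked_enrichment(metric, ["a", "c"], n_perm=10, seed=0)
        assert res.es == pytest.approx(0.75)
        np.testing.assert_allclose(
            res.running_sum,
            [0.75, 0.75 - 1 / 3, 0.75 - 1 / 3 + 0.25,
             0.75 - 1 / 3 + 0.25 - 1 / 3, 0.0],
            atol=1e-12,
        )

    def test_reversed_ranking_flips_sign(self):
        metric = pd.Series(np.arange(10, 0, -1, dtype=float),
                           index=[f"g{i}" for i in range(10)])
        top_set = ["g0", "g1", "g2"]
        res_fwd = ss.preranked_enrichment(metric, top_set, n_perm=10, seed=0)
        res_rev = ss.preranked_enrichment(-metric, top_set, n_perm=10, seed=0)
        assert res_fwd.es > 0 > res_rev.es

    def test_seed_reproducibility_bitwise(self):
        rng = np.random.default_rng(3)
        metric = pd.Series(rng.normal(size=50), index=[f"g{i}" for i in range(50)])
        gene_set = [f"g{i}" for i in range(0, 50, 7)]
        r1 = ss.preranked_enrichment(metric, gene_set, n_perm=200, seed=11)
        r2 = ss.preranked_enrichment(metric, gene_set, n_perm=200, seed=11)
        assert (r1.es, r1.nes, r1.p_perm) == (r2.es, r2.nes, r2.p_perm)

    def test_p_in_unit_interval_with_correction(self):
        metric = pd.Series([5.0, 4.0, 3.0, -3.0, -4.0],
                           index=list("abcde"))
        res = ss.preranked_enrichment(metric, ["a", "b"], n_perm=99, seed=0)
        assert 0 < res.p_perm <= 1

    def test_no_set_gene_in_ranking_is_error(self):
        metric = pd.Series([1.0], index=["a"])
        with pytest.raises(ValueError, match="no gene"):
            ss.preranked_enrichment(metric, ["zz"])

    def test_duplicate_gene_ids_rejected(self):
        metric = pd.Series([1.0, 2.0], index=["a", "a"])
        with pytest.raises(ValueError, match="duplicated"):
            ss.preranked_enrichment(metric, ["a"])


class TestEnrichmentExternalOracle:
    def test_es_matches_gseapy_prerank(self, rng):
        """The weighted running-sum ES agrees with an independent external
        implementation of the preranked method."""
        gseapy = pytest.importorskip("gseapy")
        n = 60
        metric = pd.Series(rng.normal(size=n), index=[f"g{i}" for i in range(n)])
        gene_set = [f"g{i}" for i in range(0, n, 7)]
        rnk = metric.reset_index()
        rnk.columns = ["gene", "score"]
        ext = gseapy.prerank(
            rnk=rnk, gene_sets={"S": gene_set}, permutation_num=10,
            min_size=1, max_size=100, seed=1, outdir=None, no_plot=True,
            weight=1.0,
        )
        es_ext = float(ext.res2d["ES"].iloc[0])
        mine = ss.preranked_enrichment(metric, gene_set, n_perm=10, seed=0)
        assert mine.es == pytest.approx(es_ext, abs=1e-9)


class TestSubsample:
    def test_stratified_proportions(self, annotation_factory):
        cells = [f"c{i}" for i in range(1000)]
        studies = ["s1"] * 500 + ["s2"] * 300 + ["s3"] * 200
        annot = annotation_factory(cells, studies=studies)
        idx = ss.subsample_stratified(annot, 100, seed=0)
        taken = np.asarray(studies)[idx]
        assert len(idx) == 100
        assert (taken == "s1").sum() == 50
        assert (taken == "s2").sum() == 30
        assert (taken == "s3").sum() == 20

    def test_n_larger_than_population_returns_all(self, annotation_factory):
        annot = annotation_factory([f"c{i}" for i in range(10)])
        assert len(ss.subsample_stratified(annot, 50, seed=0)) == 10
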
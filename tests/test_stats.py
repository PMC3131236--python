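"""Gene filtering, expression binning, box/t statistics, curves, subsets."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from bivalency.stats import (
    assign_expression_bins,
    bin_summary,
    detection_class_summary,
    filter_genes,
    moving_average_curve,
    spearman,
    top_quantile_subset,
)


def _scores(gene_ids, chroms=None, ratios=None, k27=None):
    n = len(gene_ids)
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "is_allosome": [c in ("chrX", "chrY") for c in (chroms or ["chr1"] * n)],
            "ratio": ratios if ratios is not None else np.ones(n),
            "k27_norm": k27 if k27 is not None else np.ones(n),
        }
    )


def _expr(gene_ids, values):
    return pd.DataFrame({"gene_id": gene_ids, "expression": values})


class TestFilterGenes:
    def test_allosome_exclusion_count(self):
        ids = [f"G{i}" for i in range(10)]
        chroms = ["chrX", "chrX"] + ["chr1"] * 8
        joined = filter_genes(_scores(ids, chroms), _expr(ids, np.arange(10.0)))
        assert len(joined) == 8

    def test_disjoint_sets_raise(self):
        with pytest.raises(ValueError, match="empty"):
            filter_genes(_scores(["A"]), _expr(["B"], [1.0]))

    def test_filtering_is_idempotent(self):
        ids = ["G1", "G2", "G3"]
        once = filter_genes(_scores(ids), _expr(ids, [1.0, 2.0, 3.0]))
        twice = filter_genes(once, _expr(ids, [1.0, 2.0, 3.0])[["gene_id"]].assign(dummy=1))
        assert list(twice["gene_id"]) == list(once["gene_id"])

    def test_partial_overlap_keeps_intersection(self):
        joined = filter_genes(
            _scores(["G1", "G2", "G3"]), _expr(["G2", "G3", "G4"], [1.0, 2.0, 3.0]),
            exclude_allosomes=False,
        )
        assert sorted(joined["gene_id"]) == ["G2", "G3"]


class TestExpressionBins:
    def test_three_way_assignment(self):
        values = np.array([0.5, 2.0, 9.0])
        # force reference mean m = 5 via a mask-selected pair (1 and 9)
        labels, m = assign_expression_bins(
            np.array([0.5, 2.0, 9.0, 1.0]), np.array([False, False, True, True])
        )
        assert m == 5.0
        assert labels.tolist() == ["below_one", "mean_to_one", "above_mean", "mean_to_one"]

    def test_value_exactly_one_is_mean_to_one(self):
        labels, _ = assign_expression_bins(
            np.array([1.0, 9.0]), np.array([True, True])
        )
        assert labels[0] == "mean_to_one"

    def test_all_below_one(self):
        labels, _ = assign_expression_bins(
            np.array([0.1, 0.2, 5.0]), np.array([False, False, True])
        )
        assert labels.tolist() == ["below_one", "below_one", "mean_to_one"]

    def test_mean_below_cut_is_configuration_error(self):
        with pytest.raises(ValueError, match="ill-ordered"):
            assign_expression_bins(np.array([0.1, 0.2]), np.array([True, True]))

    def test_bins_partition_the_gene_set(self):
        rng = np.random.default_rng(0)
        values = np.concatenate([np.zeros(30), rng.lognormal(1, 1, 70)])
        labels, _ = assign_expression_bins(values, values > 0)
        sizes = pd.Series(labels).value_counts()
        assert sizes.sum() == 100


class TestBinSummary:
    def test_box_statistics_definitional(self):
        s = bin_summary(np.array([1.0, 2, 3, 4, 5]), np.array(["above_mean"] * 5))
        b = s.bins["above_mean"]
        assert b["median"] == 3 and b["q75"] - b["q25"] == 2
        assert b["whisker_low"] == 1 and b["whisker_high"] == 5 and b["outliers"] == []

    def test_outlier_beyond_fences(self):
        vals = np.array([1.0, 2, 3, 4, 100.0])
        b = bin_summary(vals, np.array(["below_one"] * 5)).bins["below_one"]
        assert 100.0 in b["outliers"]
        assert b["whisker_high"] <= 4

    def test_identical_bins_give_null_t(self):
        ratios = np.array([1.0, 2, 3, 1, 2, 3])
        bins = np.array(["below_one"] * 3 + ["above_mean"] * 3)
        test = bin_summary(ratios, bins).tests[0]
        assert test["t"] == pytest.approx(0.0) and test["p"] == pytest.approx(1.0)

    def test_pooled_t_matches_closed_form(self):
        """Two near-constant groups: t equals the hand-computed pooled form."""
        a = np.array([1.0, 1.1, 0.9, 1.0, 1.0])
        b = np.array([2.0, 2.1, 1.9, 2.0, 2.0])
        bins = np.array(["below_one"] * 5 + ["above_mean"] * 5)
        t_obs = bin_summary(np.concatenate([a, b]), bins).tests[0]["t"]
        sp2 = ((a.var(ddof=1) * 4) + (b.var(ddof=1) * 4)) / 8
        t_hand = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / 5 + 1 / 5))
        assert t_obs == pytest.approx(t_hand, rel=1e-12)

    def test_singleton_bin_excluded_from_tests_with_warning(self):
        ratios = np.array([1.0, 2.0, 3.0])
        bins = np.array(["below_one", "above_mean", "above_mean"])
        with pytest.warns(UserWarning, match="fewer than 2"):
            s = bin_summary(ratios, bins)
        assert s.tests == []


class TestSpearman:
    def test_constant_input_reports_zero_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            r, p = spearman(np.arange(5.0), np.ones(5))
        assert r == 0.0

    def test_monotone_identity(self):
        r, _ = spearman(np.arange(20.0), np.arange(20.0) ** 2)
        assert r == pytest.approx(1.0)

    def test_exact_permutation_p_matches_scipy_permutation_test(self):
        """Small-n exact p agrees with scipy's exhaustive permutation test."""
        rng = np.random.default_rng(5)
        x = rng.normal(size=7)
        y = rng.normal(size=7)
        r, p = spearman(x, y)

        def stat(yp):
            return sps.spearmanr(x, yp).statistic

        ref = sps.permutation_test(
            (y,), stat, permutation_type="pairings", n_resamples=np.inf,
            alternative="two-sided",
        )
        assert r == pytest.approx(stat(y))
        assert p == pytest.approx(ref.pvalue, abs=1e-9)


class TestMovingAverage:
    def test_window_arithmetic(self):
        c = moving_average_curve(np.arange(4.0), np.array([1.0, 2, 3, 4]), window=2)
        assert c.y.tolist() == [1.5, 2.5, 3.5]
        assert len(c.y) == 4 - 2 + 1

    def test_window_larger_than_n_rejected(self):
        with pytest.raises(ValueError, match="smaller window"):
            moving_average_curve(np.arange(5.0), np.arange(5.0), window=10)

    def test_scale_equivariance(self):
        """Scaling ratios by c scales the curve by c, Spearman unchanged."""
        rng = np.random.default_rng(2)
        expr = rng.lognormal(size=200)
        ratios = rng.lognormal(size=200)
        base = moving_average_curve(expr, ratios, window=50)
        scaled = moving_average_curve(expr, 4.5 * ratios, window=50)
        np.testing.assert_allclose(scaled.y, 4.5 * base.y, rtol=1e-12)
        assert scaled.spearman_r == pytest.approx(base.spearman_r)

    def test_tie_breaking_by_gene_id_is_deterministic(self):
        expr = np.array([1.0, 1.0, 1.0, 2.0])
        ratios = np.array([4.0, 1.0, 2.0, 3.0])
        ids = np.array(["c", "a", "b", "d"])
        c = moving_average_curve(expr, ratios, window=2, gene_ids=ids)
        # sorted by (expression, gene_id): a,b,c,d -> ratios 1,2,4,3
        assert c.y.tolist() == [1.5, 3.0, 3.5]


class TestTopQuantile:
    @pytest.mark.parametrize("n,fraction,size", [(1844, 0.2, 369), (10, 0.25, 3), (10, 1.0, 10)])
    def test_round_half_up_size(self, n, fraction, size):
        ids = [f"G{i:05d}" for i in range(n)]
        df = _scores(ids, k27=np.arange(n, dtype=float))
        assert len(top_quantile_subset(df, fraction=fraction)) == size

    def test_selects_largest_key_values(self):
        df = _scores(["a", "b", "c", "d"], k27=np.array([5.0, 1.0, 9.0, 3.0]))
        sub = top_quantile_subset(df, fraction=0.5)
        assert sorted(sub["gene_id"]) == ["a", "c"]

    def test_boundary_ties_broken_by_gene_id(self):
        df = _scores(["b", "a", "c"], k27=np.array([1.0, 1.0, 1.0]))
        sub = top_quantile_subset(df, fraction=1 / 3)
        assert list(sub["gene_id"]) == ["a"]


class TestDetectionClasses:
    def test_single_gene_per_class(self):
        out = detection_class_summary(
            np.array([3.0, 2.0, 1.0]), np.array(["all_cells", "sporadic", "absent"])
        )
        assert [out[c]["mean"] for c in ("all_cells", "sporadic", "absent")] == [3.0, 2.0, 1.0]

    def test_empty_class_reports_none_not_zero(self):
        out = detection_class_summary(np.array([1.0]), np.array(["absent"]))
        assert out["all_cells"]["mean"] is None and out["all_cells"]["n"] == 0

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            detection_class_summary(np.array([1.0]), np.array(["sometimes"]))

    def test_class_mean_ordering_recovered_from_simulation(self, small_dataset):
        """On simulated data the mean K4/K27 ratio rises from absent through
        sporadic to all-cells genes, mirroring the coupling in the truth."""
        import bivalency as bv

        cfg, genes, expr, truth, k4, k27 = small_dataset
        scores = bv.score_genes(genes, k4, k27)
        merged = scores.merge(truth.table[["gene_id", "detection_class"]], on="gene_id")
        out = detection_class_summary(
            merged["ratio"].to_numpy(), merged["detection_class"].to_numpy()
        )
        assert out["absent"]["mean"] < out["sporadic"]["mean"] < out["all_cells"]["mean"]
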
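import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu
from sklearn.metrics import roc_auc_score

from cistromego import (DGERecord, binding_expression_curves, rank_by_de,
                        rank_product)
from cistromego.integration import (de_labels, pr_curve_points,
                                    roc_curve_points)
from cistromego.rp import rank_by_adjusted_rp


def dge(gene_id, log2fc, pvalue, padj=None):
    return DGERecord(gene_id, log2fc, pvalue, padj)


class TestRankByDE:
    def test_orders_by_ascending_pvalue(self):
        ranking = rank_by_de([dge("gA", 1, 1e-8), dge("gB", 1, 0.5)])
        assert ranking.gene_ids == ["gA", "gB"]
        assert list(ranking.ranks[["gA", "gB"]]) == [1, 2]

    def test_direction_filter_before_ranking(self):
        records = [dge("gA", +2, 0.9), dge("gB", -2, 1e-9)]
        up = rank_by_de(records, "up")
        assert up.gene_ids == ["gA"] and up.ranks["gA"] == 1

    def test_tied_pvalues_get_midranks(self):
        ranking = rank_by_de([dge("gA", 1, 0.5), dge("gB", 1, 0.5)])
        assert list(ranking.ranks[["gA", "gB"]]) == [1.5, 1.5]

    def test_empty_after_filter_is_hard_error(self):
        with pytest.raises(ValueError, match="down"):
            rank_by_de([dge("gA", +2, 0.1)], "down")


class TestRankProduct:
    def _rp(self, scores):
        return rank_by_adjusted_rp(pd.Series(scores))

    def test_product_of_recomputed_ranks(self):
        rp = self._rp({f"g{i}": 1.0 - 0.1 * i for i in range(6)})
        de = rank_by_de([dge(f"g{i}", 1, (i + 1) / 10) for i in range(6)])
        table = rank_product(rp, de)
        row = table.set_index("gene_id").loc["g2"]
        assert row["rank_product"] == row["rank_rp"] * row["rank_de"]

    def test_double_winner_is_final_rank_one(self):
        rp = self._rp({"gA": 0.9, "gB": 0.5, "gC": 0.1})
        de = rank_by_de([dge("gA", 1, 1e-6), dge("gB", 1, 0.2), dge("gC", 1, 0.9)])
        table = rank_product(rp, de)
        assert table.iloc[0]["gene_id"] == "gA"
        assert table.iloc[0]["rank_product"] == 1.0
        assert table.iloc[0]["final_rank"] == 1

    def test_universe_is_intersection(self):
        rp = self._rp({"gA": 0.9, "gB": 0.5, "gC": 0.1})
        de = rank_by_de([dge("gB", 1, 0.1), dge("gC", 1, 0.2), dge("gD", 1, 0.3)])
        table = rank_product(rp, de)
        assert set(table["gene_id"]) == {"gB", "gC"}
        # ranks recomputed within the intersection: best is 1
        assert table["rank_rp"].min() == 1.0 and table["rank_de"].min() == 1.0

    def test_symmetric_in_inputs(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(30)]
        rp = self._rp(dict(zip(genes, rng.normal(size=30))))
        de = rank_by_de([dge(g, 1, p) for g, p in zip(genes, rng.uniform(size=30))])
        a = rank_product(rp, de)
        b = rank_product(de, rp)
        pd.testing.assert_series_equal(a["rank_product"], b["rank_product"])
        assert list(a["gene_id"]) == list(b["gene_id"])

    def test_better_de_pvalue_never_worsens_final_rank(self):
        rng = np.random.default_rng(9)
        genes = [f"g{i:02d}" for i in range(20)]
        scores = dict(zip(genes, rng.normal(size=20)))
        pvals = dict(zip(genes, rng.uniform(0.1, 1.0, size=20)))
        rp = self._rp(scores)
        base = rank_product(rp, rank_by_de([dge(g, 1, pvals[g]) for g in genes]))
        rank_before = base.set_index("gene_id").loc["g07", "final_rank"]
        pvals["g07"] = 1e-6  # strictly improve one gene's DE significance
        better = rank_product(rp, rank_by_de([dge(g, 1, pvals[g]) for g in genes]))
        assert better.set_index("gene_id").loc["g07", "final_rank"] <= rank_before

    def test_disjoint_universes_hard_error(self):
        rp = self._rp({"gA": 0.9})
        de = rank_by_de([dge("gB", 1, 0.1)])
        with pytest.raises(ValueError):
            rank_product(rp, de)


class TestCurves:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([True, True, False, False])
        roc = roc_curve_points(scores, labels)
        assert roc.auc == pytest.approx(1.0)
        assert roc.x[0] == 0.0 and roc.y[0] == 0.0
        assert roc.x[-1] == 1.0 and roc.y[-1] == 1.0

    def test_perfect_anti_separation(self):
        roc = roc_curve_points(np.array([0.1, 0.9]), np.array([True, False]))
        assert roc.auc == pytest.approx(0.0)

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(10)
        n = 10_000
        scores = rng.normal(size=n)
        labels = rng.random(n) < 0.3
        roc = roc_curve_points(scores, labels)
        assert roc.auc == pytest.approx(0.5, abs=0.02)

    def test_auc_equals_mann_whitney_u(self):
        """Threshold-sweep AUROC is the Mann-Whitney U statistic divided by
        n_pos * n_neg, including under heavy score ties."""
        rng = np.random.default_rng(8)
        for _ in range(10):
            n = 200
            scores = np.round(rng.normal(size=n), 1)  # force ties
            labels = rng.random(n) < 0.4
            roc = roc_curve_points(scores, labels)
            u = mannwhitneyu(scores[labels], scores[~labels]).statistic
            expected = u / (labels.sum() * (~labels).sum())
            assert roc.auc == pytest.approx(expected, rel=1e-12)
            assert roc.auc == pytest.approx(roc_auc_score(labels, scores), rel=1e-12)

    def test_pr_anchor_uses_top_prediction(self):
        scores = np.array([0.9, 0.8, 0.2])
        pr_hit = pr_curve_points(scores, np.array([True, False, False]))
        assert pr_hit.y[0] == 1.0
        pr_miss = pr_curve_points(scores, np.array([False, True, False]))
        assert pr_miss.y[0] == 0.0
        assert 0 <= pr_hit.auc <= 1

    def test_label_rule_padj_with_pvalue_fallback(self):
        labels = de_labels(
            [dge("gA", 1, 0.001, 0.01), dge("gB", 1, 0.001, 0.9),
             dge("gC", 1, 0.01, None), dge("gD", -1, 0.001, 0.01)],
            cutoff=0.05, direction="up")
        assert labels == {"gA": True, "gB": False, "gC": True, "gD": False}

    def test_degenerate_labels_hard_error(self):
        adj = {"gA": 0.5, "gB": 0.2}
        all_pos = [dge("gA", 1, 1e-9, 1e-8), dge("gB", 1, 1e-9, 1e-8)]
        with pytest.raises(ValueError):
            binding_expression_curves(adj, all_pos)

    def test_curves_on_named_genes(self):
        adj = {"gA": 0.9, "gB": 0.6, "gC": 0.1, "gD": 0.0}
        records = [dge("gA", 2, 1e-8, 1e-6), dge("gB", 2, 1e-8, 1e-6),
                   dge("gC", 0.1, 0.9, 0.95), dge("gD", 0.1, 0.8, 0.95)]
        roc, pr = binding_expression_curves(adj, records)
        assert roc.auc == pytest.approx(1.0)
        assert pr.auc == pytest.approx(1.0)
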
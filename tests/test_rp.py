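import numpy as np
import pandas as pd
import pytest

from cistromego import (DecayConfig, GeneAnnotation, adjust_rp, compute_baseline,
                        peak_weight, rank_by_adjusted_rp, raw_rp, raw_rp_all,
                        scale_rp)
from conftest import brute_force_rp, make_peak, random_gene_peak_fixture


class TestPeakWeight:
    @pytest.mark.parametrize("distance,expected", [
        (0, 1.0),          # unit weight at the TSS
        (1000, 0.5),       # half weight at d0
        (2000, 0.25),      # 2**-2 at 2*d0
    ])
    def test_half_life_form(self, decay_1kb, distance, expected):
        assert peak_weight(distance, decay_1kb) == pytest.approx(expected, rel=1e-12)

    def test_strictly_decreasing(self, decay_1kb):
        d = np.linspace(0, 15_000, 100)
        w = peak_weight(d, decay_1kb)
        assert np.all(np.diff(w) < 0)

    def test_negative_distance_rejected(self, decay_1kb):
        with pytest.raises(ValueError):
            peak_weight(-1, decay_1kb)

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            DecayConfig(d0=0)


class TestRawRP:
    def test_two_peak_sum(self, decay_1kb):
        peaks = [make_peak("chr1", 100_000), make_peak("chr1", 101_000)]
        # weights 1.0 (at TSS) + 0.5 (at d0)
        assert raw_rp([("chr1", 100_000)], peaks, decay_1kb) == pytest.approx(1.5)

    def test_no_peaks_in_window_is_zero(self, decay_1kb):
        peaks = [make_peak("chr1", 500_000)]
        assert raw_rp([("chr1", 100_000)], peaks, decay_1kb) == 0.0

    def test_window_boundary_inclusive(self, decay_1kb):
        peaks = [make_peak("chr1", 100_000 + 15_000)]  # exactly 15*d0 away
        rp = raw_rp([("chr1", 100_000)], peaks, decay_1kb)
        assert rp == pytest.approx(2.0 ** -15, rel=1e-12)

    def test_other_chromosome_ignored(self, decay_1kb):
        peaks = [make_peak("chr2", 100_000)]
        assert raw_rp([("chr1", 100_000)], peaks, decay_1kb) == 0.0

    def test_multi_tss_takes_maximum(self, decay_1kb):
        peaks = [make_peak("chr1", 100_000)]
        rp = raw_rp([("chr1", 100_000), ("chr1", 101_000)], peaks, decay_1kb)
        assert rp == pytest.approx(1.0)  # best TSS sits on the peak

    def test_indexed_equals_brute_force(self, decay_1kb):
        rng = np.random.default_rng(42)
        for _ in range(20):
            genes, peaks = random_gene_peak_fixture(rng)
            fast = raw_rp_all(genes, peaks, decay_1kb)
            oracle = brute_force_rp(genes, peaks, decay_1kb)
            for gid, val in oracle.items():
                assert fast[gid] == pytest.approx(val, rel=1e-12, abs=1e-300)

    def test_moving_peak_closer_never_decreases_rp(self, decay_1kb):
        tss = 100_000
        for d in [14_000, 9_000, 4_000, 1_000, 0]:
            closer = raw_rp([("chr1", tss)], [make_peak("chr1", tss + d)], decay_1kb)
            farther = raw_rp([("chr1", tss)], [make_peak("chr1", tss + d + 500)],
                             decay_1kb)
            assert closer >= farther

    def test_translation_invariance(self, decay_1kb):
        rng = np.random.default_rng(7)
        genes, peaks = random_gene_peak_fixture(rng, n_genes=20, n_peaks=50)
        shift = 12_345
        genes2 = [GeneAnnotation(g.gene_id, g.chrom, g.tss + shift, g.strand)
                  for g in genes]
        peaks2 = [make_peak(p.chrom, p.center + shift) for p in peaks]
        a = raw_rp_all(genes, peaks, decay_1kb)
        b = raw_rp_all(genes2, peaks2, decay_1kb)
        assert np.allclose(a.values, b.values, rtol=1e-12)


class TestScaleAdjustRank:
    def test_min_max_scaling(self):
        out = scale_rp(pd.Series([0.0, 1.0, 3.0], index=list("abc")))
        assert list(out) == pytest.approx([0.0, 1 / 3, 1.0])

    @pytest.mark.parametrize("values", [[5.0], [2.0, 2.0, 2.0]])
    def test_degenerate_all_equal_scales_to_zero(self, values):
        out = scale_rp(pd.Series(values))
        assert (out == 0.0).all()

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        x = pd.Series(rng.uniform(0, 10, 50))
        assert np.allclose(scale_rp(3.5 * x + 2.0), scale_rp(x))
        assert scale_rp(x).between(0, 1).all()

    def test_adjustment_subtracts_baseline(self):
        scaled = pd.Series({"gA": 0.8, "gB": 0.2, "gC": 0.4})
        adj = adjust_rp(scaled, {"gA": 0.3, "gB": 0.6})
        assert adj["gA"] == pytest.approx(0.5)
        assert adj["gB"] == pytest.approx(-0.4)  # negative allowed
        assert adj["gC"] == pytest.approx(0.4)   # absent gene -> baseline 0

    def test_no_baseline_is_identity(self):
        scaled = pd.Series({"gA": 0.8, "gB": 0.2})
        assert adjust_rp(scaled, None).equals(scaled)

    def test_ranking_descending_with_midranks(self):
        adj = pd.Series({"gA": 0.5, "gB": 0.5, "gC": 0.1})
        ranking = rank_by_adjusted_rp(adj)
        assert ranking.ranks["gA"] == ranking.ranks["gB"] == 1.5
        assert ranking.ranks["gC"] == 3
        assert ranking.gene_ids == ["gA", "gB", "gC"]  # ties: gene_id order

    def test_all_tied_ranks_are_average(self):
        adj = pd.Series({"gA": 0.2, "gB": 0.2, "gC": 0.2})
        ranking = rank_by_adjusted_rp(adj)
        assert set(ranking.ranks) == {2.0}  # (G+1)/2

    def test_ranks_are_permutation_when_no_ties(self):
        rng = np.random.default_rng(0)
        adj = pd.Series(rng.normal(size=30), index=[f"g{i}" for i in range(30)])
        ranking = rank_by_adjusted_rp(adj)
        assert sorted(ranking.ranks) == list(range(1, 31))


class TestBaseline:
    def test_single_dataset_median_is_itself(self, tiny_genes, decay_1kb):
        peaks = [make_peak("chr1", 100_000), make_peak("chr2", 200_000)]
        base = compute_baseline([peaks], tiny_genes, decay_1kb)
        scaled = scale_rp(raw_rp_all(tiny_genes, peaks, decay_1kb))
        assert base == pytest.approx(scaled.to_dict())

    def test_median_across_datasets(self, tiny_genes, decay_1kb):
        sets = [
            [make_peak("chr1", 100_000)],                          # gA scaled 1
            [make_peak("chr1", 100_000), make_peak("chr1", 100_100)],
            [make_peak("chr2", 100_000)],                          # gA scaled 0
        ]
        base = compute_baseline(sets, tiny_genes, decay_1kb)
        # gA scaled values are 1, 1, 0 -> median 1
        assert base["gA"] == pytest.approx(1.0)
        assert base["gD"] == pytest.approx(0.0)

    def test_empty_panel_is_error(self, tiny_genes, decay_1kb):
        with pytest.raises(ValueError):
            compute_baseline([], tiny_genes, decay_1kb)
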
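from math import comb

import numpy as np
import pytest

import narpipe as npk
from narpipe.enrichment import adjust_results, density_enrichment, format_p
from helpers import gene_df, make_domains


class TestPartitionGenes:
    nars = make_domains([("chr1", 1_000, 2_000)])

    def test_fully_inside(self):
        g = gene_df([("a", "chr1", 1_100, 1_500, "+", True, "unchanged")])
        assert npk.partition_genes(g, self.nars).tolist() == [True]

    def test_zero_overlap(self):
        g = gene_df([("a", "chr1", 5_000, 6_000, "+", True, "unchanged")])
        assert npk.partition_genes(g, self.nars).tolist() == [False]

    def test_forty_percent_covered_is_outside(self):
        # gene [1600, 2600): only [1600, 2000) = 40% lies inside the domain
        g = gene_df([("a", "chr1", 1_600, 2_600, "+", True, "unchanged")])
        assert npk.partition_genes(g, self.nars, rule="coverage").tolist() == [False]

    def test_exactly_half_is_outside(self):
        g = gene_df([("a", "chr1", 500, 1_500, "+", True, "unchanged")])
        assert npk.partition_genes(g, self.nars).tolist() == [False]

    def test_tss_rule_uses_strand(self):
        g = gene_df(
            [
                ("fwd", "chr1", 1_500, 5_000, "+", True, "unchanged"),
                ("rev", "chr1", 1_500, 5_000, "-", True, "unchanged"),
            ]
        )
        inside = npk.partition_genes(g, self.nars, rule="tss")
        assert inside.tolist() == [True, False]

    def test_any_rule(self):
        g = gene_df([("a", "chr1", 600, 1_600, "+", True, "unchanged")])
        assert npk.partition_genes(g, self.nars, rule="any").tolist() == [True]

    def test_partition_is_exhaustive(self, genes, nars):
        inside = npk.partition_genes(genes, nars)
        assert len(inside) == len(genes)


def fisher_two_sided_oracle(table):
    """Exact two-sided p by enumeration over all tables with fixed margins."""
    a, b = table[0]
    c, d = table[1]
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def prob(x):
        return comb(row1, x) * comb(row2, col1 - x) / comb(n, col1)

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, col1 - row2), min(row1, col1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return total


class TestCategoricalEnrichment:
    def test_symmetric_table(self):
        label = np.array([True] * 50 + [False] * 50 + [True] * 50 + [False] * 50)
        inside = np.array([True] * 100 + [False] * 100)
        r = npk.categorical_enrichment(label, inside)
        assert r.statistic == pytest.approx(1.0)
        assert r.p_value == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self):
        table = [[63, 37], [40, 60]]
        label = np.array([True] * 63 + [False] * 37 + [True] * 40 + [False] * 60)
        inside = np.array([True] * 100 + [False] * 100)
        r = npk.categorical_enrichment(label, inside)
        assert r.p_value == pytest.approx(fisher_two_sided_oracle(table), rel=1e-9)

    def test_degenerate_label_rejected(self):
        label = np.ones(10, dtype=bool)
        inside = np.array([True] * 5 + [False] * 5)
        with pytest.raises(ValueError, match="label"):
            npk.categorical_enrichment(label, inside)

    def test_empty_partition_rejected(self):
        label = np.array([True, False])
        inside = np.array([True, True])
        with pytest.raises(ValueError, match="partition"):
            npk.categorical_enrichment(label, inside)


class TestSignalEnrichment:
    nars = make_domains([("chr1", 0, 50_000)])

    def grid(self, n):
        chroms = np.array(["chr1"] * n, dtype=object)
        positions = np.arange(n) * 35
        return chroms, positions

    def test_null_t_is_small(self, rng):
        chroms, positions = self.grid(10_000)
        values = rng.normal(size=10_000)
        r = npk.signal_enrichment(chroms, positions, values, self.nars)
        assert abs(r.statistic) < 3

    def test_shifted_signal_detected(self, rng):
        n = 2_000
        chroms, positions = self.grid(n)
        inside = positions < 50_000
        values = rng.normal(size=n) + inside * 1.0
        r = npk.signal_enrichment(chroms, positions, values, self.nars)
        assert r.p_value < 1e-6
        assert r.inside_summary > r.outside_summary

    def test_swap_negates_t(self, rng):
        n = 1_000
        chroms, positions = self.grid(n)
        half = make_domains([("chr1", 0, 17_500)])
        complement = make_domains([("chr1", 17_500, 35 * n)])
        values = rng.normal(size=n) + (positions < 17_500) * 0.5
        r_in = npk.signal_enrichment(chroms, positions, values, half)
        r_out = npk.signal_enrichment(chroms, positions, values, complement)
        assert r_in.statistic == pytest.approx(-r_out.statistic, rel=1e-9)

    def test_constant_signal_rejected(self):
        chroms, positions = self.grid(100)
        half = make_domains([("chr1", 0, 1_750)])
        with pytest.raises(ValueError, match="constant"):
            npk.signal_enrichment(chroms, positions, np.ones(100), half)


class TestGeneDensity:
    def test_no_genes_zero_density(self):
        track = npk.gene_density_track(gene_df([]), {"chr1": 100_000})
        assert (track["count"] == 0).all()

    def test_regular_genes_count(self):
        # one 1 kb gene every 10 kb: a 20 kb window overlaps 2 or 3 of them
        genes = gene_df(
            [(f"g{i}", "chr1", i * 10_000, i * 10_000 + 1_000, "+", True, "unchanged") for i in range(50)]
        )
        track = npk.gene_density_track(genes, {"chr1": 500_000})
        assert set(track["count"].unique()) <= {2, 3}

    def test_offset_halves_windows(self):
        genes = gene_df([])
        t1 = npk.gene_density_track(genes, {"chr1": 200_000}, offset_bp=1_000)
        t2 = npk.gene_density_track(genes, {"chr1": 200_000}, offset_bp=2_000)
        assert abs(len(t1) - 2 * len(t2)) <= 1

    def test_window_must_exceed_offset(self):
        with pytest.raises(ValueError):
            npk.gene_density_track(gene_df([]), {"chr1": 100_000}, window_bp=500, offset_bp=1_000)

    def test_wilcoxon_detects_planted_density_contrast(self, genes, nars):
        track = npk.gene_density_track(genes, {"chr1": 2_000_000, "chr2": 2_000_000})
        r = density_enrichment(track, nars)
        assert r.test == "wilcoxon"
        assert 0 <= r.p_value <= 1


class TestTssWindows:
    def test_forward_strand_clipped_at_zero(self):
        g = gene_df([("a", "chr1", 100, 900, "+", True, "unchanged")])
        t = npk.tss_window_track(g, 1_000)
        assert t.iloc[0]["start"] == 0
        assert t.iloc[0]["end"] == 600

    def test_reverse_strand_centred_on_end(self):
        g = gene_df([("a", "chr1", 100, 900, "-", True, "unchanged")])
        t = npk.tss_window_track(g, 1_000)
        assert t.iloc[0]["start"] == 400
        assert t.iloc[0]["end"] == 1_400

    def test_empty_input(self):
        assert len(npk.tss_window_track(gene_df([]))) == 0

    def test_missing_strand_rejected(self):
        g = gene_df([("a", "chr1", 100, 900, ".", True, "unchanged")])
        with pytest.raises(ValueError, match="strand"):
            npk.tss_window_track(g)

    def test_clipped_at_chromosome_end(self):
        g = gene_df([("a", "chr1", 100, 900, "-", True, "unchanged")])
        t = npk.tss_window_track(g, 1_000, {"chr1": 1_000})
        assert t.iloc[0]["end"] == 1_000


class TestCooccurrence:
    def test_identical_tracks(self, rng):
        v = rng.normal(size=1_000)
        out = npk.marker_cooccurrence(v, v, 1.0, 1.0)
        assert out["fraction_both"] == out["fraction_a"]

    def test_disjoint_masks(self):
        a = np.array([1.0] * 50 + [0.0] * 50)
        b = np.array([0.0] * 50 + [1.0] * 50)
        out = npk.marker_cooccurrence(a, b, 0.5, 0.5)
        assert out["fraction_both"] == 0.0
        assert out["odds_ratio"] < 1

    def test_independent_masks_product(self, rng):
        n = 100_000
        a = rng.random(n)
        b = rng.random(n)
        out = npk.marker_cooccurrence(a, b, 0.7, 0.7)  # 30% marginals
        assert out["fraction_both"] == pytest.approx(0.09, abs=0.01)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            npk.marker_cooccurrence(np.ones(5), np.ones(6), 0.5, 0.5)


class TestBhFdr:
    def test_single_p(self):
        assert npk.bh_fdr([0.04])[0] == pytest.approx(0.04)

    def test_three_value_example(self):
        q = npk.bh_fdr([0.01, 0.02, 0.03])
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert np.allclose(npk.bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            npk.bh_fdr([0.5, 1.5])

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(200)
        q = npk.bh_fdr(p)
        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(q, q_ref)

    def test_q_at_least_p(self, rng):
        p = rng.random(50)
        assert (npk.bh_fdr(p) >= p - 1e-12).all()


class TestResultPlumbing:
    def test_adjust_results_fills_q(self, genes, nars):
        inside = npk.partition_genes(genes, nars)
        results = [
            npk.categorical_enrichment(genes["expressed"].to_numpy(), inside, "expr"),
            npk.categorical_enrichment((genes["de_status"] == "down").to_numpy(), inside, "down"),
        ]
        adjust_results(results)
        for r in results:
            assert r.q_value is not None and r.q_value >= r.p_value - 1e-12

    def test_p_floor_formatting(self):
        assert format_p(1e-20) == "<2.2e-16"
        assert format_p(0.5) == "0.5"

    def test_direction_agreement_on_planted_data(self, genes, nars, profile):
        inside = npk.partition_genes(genes, nars)
        cat = npk.categorical_enrichment(genes["expressed"].to_numpy(), inside, "expr")
        sig = npk.signal_enrichment(profile.chroms, profile.positions, profile.smoothed, nars)
        assert (cat.statistic > 1) == (sig.inside_summary > sig.outside_summary)
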
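import numpy as np
import pandas as pd
import pytest

import narpipe as npk
from narpipe.caller import DensityTrack, DomainSet, probe_agreement
from narpipe.tiling import BindingProfile
from helpers import make_domains


def profile_from_signs(signs, spacing=100, chrom="chr1"):
    signs = np.asarray(signs, dtype=float)
    vals = np.where(signs > 0, 1.0, -1.0)
    chroms = np.array([chrom] * len(vals), dtype=object)
    return BindingProfile(chroms, np.arange(len(vals)) * spacing, vals, smoothed=vals, spacing=spacing)


def density_track(density, spacing=35, window=10_000, chrom="chr1"):
    density = np.asarray(density, dtype=float)
    chroms = np.array([chrom] * len(density), dtype=object)
    return DensityTrack(chroms, np.arange(len(density)) * spacing, density, window, spacing=spacing)


class TestDensity:
    def test_all_positive(self):
        p = profile_from_signs(np.ones(50))
        d = npk.positive_probe_density(p, 1_000)
        assert np.allclose(d.density, 1.0)

    def test_none_positive(self):
        p = profile_from_signs(-np.ones(50))
        d = npk.positive_probe_density(p, 1_000)
        assert np.allclose(d.density, 0.0)

    def test_alternating_parity(self):
        # 11 probes alternating +/- starting positive, window spanning all
        signs = np.array([1, -1] * 5 + [1])
        p = profile_from_signs(signs, spacing=10)
        d = npk.positive_probe_density(p, 10_000)
        assert np.allclose(d.density, 6 / 11)
        p2 = profile_from_signs(-signs, spacing=10)
        d2 = npk.positive_probe_density(p2, 10_000)
        assert np.allclose(d2.density, 5 / 11)

    def test_empty_profile(self):
        p = BindingProfile(np.array([], dtype=object), np.array([], dtype=int), np.array([]))
        d = npk.positive_probe_density(p, 10_000)
        assert len(d.density) == 0

    def test_window_truncated_at_ends(self):
        signs = np.array([1, 1, -1, -1])
        p = profile_from_signs(signs, spacing=100)
        d = npk.positive_probe_density(p, 300)  # probe 0 sees probes 0,1 only
        assert d.density[0] == pytest.approx(1.0)


class TestCallDomains:
    def test_density_one_gives_single_domain_per_chromosome(self):
        chroms = np.array(["chr1"] * 5 + ["chr2"] * 5, dtype=object)
        positions = np.concatenate([np.arange(5) * 35, np.arange(5) * 35])
        d = DensityTrack(chroms, positions, np.ones(10), 10_000, spacing=35)
        out = npk.call_domains(d, 0.70)
        assert len(out) == 2
        assert set(out.domains["chrom"]) == {"chr1", "chr2"}

    def test_exact_threshold_excluded(self):
        d = density_track(np.full(20, 0.70))
        assert len(npk.call_domains(d, 0.70)) == 0

    def test_toy_run_spans_probes_10_to_21(self):
        # 30 probes at 100 bp spacing, window 300 bp (probe +/- one neighbour):
        # probes 9..22 positive makes the 3-of-3 qualifying run exactly 10..21
        signs = -np.ones(30)
        signs[9:23] = 1
        p = profile_from_signs(signs, spacing=100)
        d = npk.positive_probe_density(p, 300)
        out = npk.call_domains(d, 0.70)
        assert len(out) == 1
        dom = out.domains.iloc[0]
        assert dom["start"] == 10 * 100
        assert dom["end"] == 21 * 100 + 100
        assert dom["n_probes"] == 12

    def test_gap_tolerance_merges_runs(self):
        dens = np.concatenate([np.ones(5), [0.0], np.ones(5)])
        d = density_track(dens)
        assert len(npk.call_domains(d, 0.70, max_gap_probes=0)) == 2
        assert len(npk.call_domains(d, 0.70, max_gap_probes=1)) == 1

    def test_windows_extent_widens_domains(self):
        dens = np.concatenate([np.zeros(10), np.ones(10), np.zeros(10)])
        d = density_track(dens, spacing=35, window=1_000)
        probes = npk.call_domains(d, 0.70, extent="probes")
        windows = npk.call_domains(d, 0.70, extent="windows")
        assert windows.total_bp > probes.total_bp

    def test_theta_out_of_range(self, density):
        with pytest.raises(ValueError):
            npk.call_domains(density, 1.5)

    def test_monotone_in_theta(self, density):
        bps = [npk.call_domains(density, t).total_bp for t in (0.5, 0.6, 0.7, 0.8, 0.9)]
        assert all(a >= b for a, b in zip(bps, bps[1:]))


class TestShuffle:
    def test_preserves_positive_count_and_positions(self, profile):
        sh = npk.shuffle_binding(profile, 3)
        assert sh.is_positive.sum() == profile.is_positive.sum()
        assert np.array_equal(sh.positions, profile.positions)

    def test_seed_reproducible(self, profile):
        a = npk.shuffle_binding(profile, 5)
        b = npk.shuffle_binding(profile, 5)
        assert np.array_equal(a.smoothed, b.smoothed)

    def test_different_seed_differs(self, profile):
        a = npk.shuffle_binding(profile, 5)
        b = npk.shuffle_binding(profile, 6)
        assert not np.array_equal(a.smoothed, b.smoothed)


class TestTwoStage:
    def test_degenerate_parameters_match_single_stage(self, density):
        single = npk.call_domains(density, 0.70)
        two = npk.call_domains_two_stage(density, 0.70, 0.70)
        pd.testing.assert_frame_equal(single.domains, two.domains)

    def test_no_seeds_empty(self):
        d = density_track(np.full(20, 0.65))
        assert len(npk.call_domains_two_stage(d, 0.80, 0.60)) == 0

    def test_agreement_with_single_stage(self, density, profile):
        base = npk.call_domains(density, 0.70)
        two = npk.call_domains_two_stage(density, 0.80, 0.60)
        agreement = probe_agreement(base, two, profile.chroms, profile.positions)
        assert agreement >= 0.80

    def test_rejects_bad_thresholds(self, density):
        with pytest.raises(ValueError):
            npk.call_domains_two_stage(density, 0.6, 0.8)
        with pytest.raises(ValueError):
            npk.call_domains_two_stage(density, 1.2, 0.6)


class TestOverlap:
    def test_identical_sets(self):
        a = make_domains([("chr1", 0, 100), ("chr2", 50, 150)])
        rep = npk.domain_overlap(a, a)
        assert rep["fraction_a_in_b"] == 1.0
        assert rep["fraction_b_in_a"] == 1.0
        assert rep["jaccard"] == 1.0

    def test_disjoint_sets(self):
        a = make_domains([("chr1", 0, 100)])
        b = make_domains([("chr1", 200, 300)])
        rep = npk.domain_overlap(a, b)
        assert rep["shared_bp"] == 0
        assert rep["jaccard"] == 0.0

    def test_half_overlap_example(self):
        a = make_domains([("chr1", 0, 100)])
        b = make_domains([("chr1", 50, 150)])
        rep = npk.domain_overlap(a, b)
        assert rep["shared_bp"] == 50
        assert rep["jaccard"] == pytest.approx(1 / 3)

    def test_unknown_chromosome_rejected(self):
        a = make_domains([("chrZ", 0, 100)])
        b = make_domains([("chr1", 0, 100)])
        with pytest.raises(ValueError, match="chromosome"):
            npk.domain_overlap(a, b, genome={"chr1": 1000})


class TestOccupancy:
    def test_quarter_occupancy(self):
        d = make_domains([("chr1", 0, 250_000)])
        out = npk.occupancy_stats(d, {"chr1": 1_000_000})
        row = out[out["group"] == "chr1"].iloc[0]
        assert row["occupancy_pct"] == pytest.approx(25.0)

    def test_empty_set(self):
        d = make_domains([])
        out = npk.occupancy_stats(d, {"chr1": 1_000_000})
        assert (out["occupancy_pct"] == 0).all()
        assert out["median_length"].isna().all()

    def test_median_of_two_domains(self):
        d = make_domains([("chr1", 0, 10_000), ("chr1", 50_000, 80_000)])
        out = npk.occupancy_stats(d, {"chr1": 1_000_000})
        row = out[out["group"] == "chr1"].iloc[0]
        assert row["median_length"] == pytest.approx(20_000)

    def test_out_of_bounds_domain_rejected(self):
        d = make_domains([("chr1", 0, 2_000_000)])
        with pytest.raises(ValueError, match="bounds"):
            npk.occupancy_stats(d, {"chr1": 1_000_000})

    def test_grouping_must_partition(self):
        d = make_domains([("chr1", 0, 100)])
        with pytest.raises(ValueError, match="partition"):
            npk.occupancy_stats(d, {"chr1": 1000, "chr2": 1000}, {"only": ["chr1"]})

    def test_grouped_occupancy(self):
        d = make_domains([("chrX", 0, 600_000), ("chr2", 0, 100_000)])
        out = npk.occupancy_stats(
            d, {"chrX": 1_000_000, "chr2": 1_000_000}, {"X": ["chrX"], "autosomes": ["chr2"]}
        )
        by_group = out.set_index("group")
        assert by_group.loc["X", "occupancy_pct"] == pytest.approx(60.0)
        assert by_group.loc["autosomes", "occupancy_pct"] == pytest.approx(10.0)


class TestDomainSetInvariants:
    def test_overlapping_domains_rejected(self):
        with pytest.raises(ValueError):
            make_domains([("chr1", 0, 100), ("chr1", 50, 200)])

    def test_empty_interval_rejected(self):
        with pytest.raises(ValueError):
            make_domains([("chr1", 100, 100)])
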
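"""Landscape statistics: per-class stats, proportions, gaps, hotspots,
permutation null, and sequence contexts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import m6amap as m
from m6amap.annotation import ClassInterval, FeatureClassSet
from m6amap.landscape import motif_matches, site_context

from conftest import brute_force_hotspots, make_sites


class TestFeatureStats:
    @pytest.fixture
    def genome(self):
        #         0123456789
        # chr1 = "AAGCTAGCTA": A at 0,1,5,9 (+); T at 4,8 (-)
        return m.Genome({"chr1": "AAGCTAGCTA"})

    def _classes(self, stranded=True, strand="+"):
        fcs = FeatureClassSet("X", stranded=stranded)
        fcs.intervals = [ClassInterval("chr1", 0, 10, strand if stranded else None, "u1")]
        return {"X": fcs}

    def test_density_counts_strand_adenines_only(self, genome):
        sites = [m.MethylationSite("chr1", 0, "+")]
        stats = m.feature_methylation_stats(sites, self._classes(), genome)
        s = stats["X"]
        assert s.n_adenines == 4 and s.n_6ma == 1
        assert s.density_6ma_per_a == 0.25
        assert s.frac_fragments_methylated == 1.0

    def test_opposite_strand_site_does_not_count(self, genome):
        sites = [m.MethylationSite("chr1", 4, "-")]
        stats = m.feature_methylation_stats(sites, self._classes(), genome)
        assert stats["X"].n_6ma == 0
        assert stats["X"].frac_fragments_methylated == 0.0

    def test_fragment_fraction_over_two_units(self, genome):
        fcs = FeatureClassSet("X")
        fcs.intervals = [
            ClassInterval("chr1", 0, 5, "+", "u1"),
            ClassInterval("chr1", 5, 10, "+", "u2"),
        ]
        sites = [m.MethylationSite("chr1", 0, "+")]
        stats = m.feature_methylation_stats(sites, {"X": fcs}, genome)
        assert stats["X"].n_fragments == 2
        assert stats["X"].frac_fragments_methylated == 0.5

    def test_unstranded_class_pools_both_strands(self, genome):
        sites = [m.MethylationSite("chr1", 0, "+"), m.MethylationSite("chr1", 4, "-")]
        stats = m.feature_methylation_stats(
            sites, self._classes(stranded=False), genome
        )
        assert stats["X"].n_adenines == 6 and stats["X"].n_6ma == 2


class TestCompareProportions:
    def test_closed_form_value(self):
        z, p = m.compare_proportions(50, 100, 25, 100)
        assert z == pytest.approx(3.6515, abs=5e-5)

    def test_identity_case(self):
        z, p = m.compare_proportions(10, 100, 10, 100)
        assert z == 0 and p == 1

    def test_extreme_case(self):
        z, _ = m.compare_proportions(0, 10, 10, 10)
        assert abs(z) == pytest.approx(4.4721, abs=5e-5)

    def test_invalid_counts_raise(self):
        with pytest.raises(ValueError):
            m.compare_proportions(11, 10, 1, 10)


class TestIntersiteIntervals:
    def test_gaps_and_fraction_below(self, tiny_genome):
        g = m.Genome({"c": "A" * 3000})
        sites = make_sites(g, "c", [100, 300, 2500], strand="+")
        gaps = m.intersite_intervals(sites)
        assert gaps.all_gaps.tolist() == [200, 2200]
        assert gaps.fraction_below(2000) == 0.5

    def test_single_site_per_chromosome_gives_no_gaps(self):
        sites = [m.MethylationSite("c1", 5, "+"), m.MethylationSite("c2", 9, "+")]
        gaps = m.intersite_intervals(sites)
        assert gaps.all_gaps.size == 0
        assert gaps.fraction_below(2000) is None

    def test_no_cross_chromosome_gaps(self):
        sites = [m.MethylationSite("c1", 0, "+"), m.MethylationSite("c2", 1, "+"),
                 m.MethylationSite("c2", 50, "-")]
        gaps = m.intersite_intervals(sites)
        assert gaps.all_gaps.tolist() == [49]


class TestHotspots:
    def test_minimal_satisfying_run(self):
        g = m.Genome({"c": "A" * 500})
        sites = make_sites(g, "c", range(0, 500, 50), strand="+")
        (h,) = m.call_hotspots(sites)
        assert (h.start, h.end, h.n_sites) == (0, 451, 10)

    def test_nine_sites_is_below_minimum(self):
        g = m.Genome({"c": "A" * 500})
        sites = make_sites(g, "c", range(0, 450, 50), strand="+")
        assert m.call_hotspots(sites) == []

    def test_gap_of_exactly_100_splits_runs(self):
        g = m.Genome({"c": "A" * 2000})
        positions = list(range(0, 500, 50)) + [550 + 50 * i for i in range(10)]
        # gap between 450 and 550 is exactly 100: strict < rule splits
        sites = make_sites(g, "c", positions, strand="+")
        hs = m.call_hotspots(sites)
        assert [h.n_sites for h in hs] == [10, 10]
        assert brute_force_hotspots(positions) == [
            (h.start, h.end, h.n_sites) for h in hs
        ]

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.integers(0, 3000), min_size=0, max_size=120, unique=True))
    def test_matches_brute_force_scan(self, positions):
        sites = [m.MethylationSite("c", p, "+") for p in positions]
        called = [(h.start, h.end, h.n_sites) for h in m.call_hotspots(sites)]
        assert called == brute_force_hotspots(positions)


class TestPermutation:
    def _hotspot(self, chrom, start, length):
        return m.landscape.HotspotCall(chrom, start, start + length, 10, 50)

    def test_te_saturation_gives_p_one(self):
        g = m.Genome({"c": "A" * 10_000})
        tes = [m.RepeatFeature("c", 0, 10_000, "TE", "DNA/CMC-EnSpm")]
        res = m.hotspot_te_permutation(
            [self._hotspot("c", 100, 500)], tes, g, n_perm=50, seed=0
        )
        assert res.observed_fraction == 1.0
        assert res.null_mean == 1.0
        assert res.p_value == 1.0

    def test_no_tes_gives_observed_zero(self):
        g = m.Genome({"c": "A" * 10_000})
        res = m.hotspot_te_permutation(
            [self._hotspot("c", 100, 500)], [], g, n_perm=50, seed=0
        )
        assert res.observed_fraction == 0.0 and res.p_value == 1.0

    def test_null_mean_matches_analytic_overlap_probability(self):
        """One chromosome, one TE, fixed hotspot length: the relocation null
        mean equals the closed-form overlap probability for a uniform
        start."""
        N, L = 20_000, 400
        a, b = 8000, 9000
        g = m.Genome({"c": "A" * N})
        tes = [m.RepeatFeature("c", a, b, "TE", "LTR/Gypsy")]
        res = m.hotspot_te_permutation(
            [self._hotspot("c", 0, L)], tes, g, n_perm=10_000, seed=3
        )
        starts = N - L + 1
        n_hit = min(N - L, b - 1) - max(0, a - L + 1) + 1
        p_analytic = n_hit / starts
        se = np.sqrt(p_analytic * (1 - p_analytic) / 10_000)
        assert abs(res.null_mean - p_analytic) <= 3 * se

    def test_oversized_hotspot_raises(self):
        g = m.Genome({"c": "A" * 100})
        with pytest.raises(ValueError):
            m.hotspot_te_permutation(
                [self._hotspot("c", 0, 200)],
                [m.RepeatFeature("c", 0, 10, "TE", "x")], g, n_perm=5, seed=0,
            )


class TestContextStats:
    def test_motif_match_on_plus_context(self):
        #            4 flank  A G G C A
        ctx = "TTTT" + "AGGCA"
        assert motif_matches(ctx, "AGGYV", a_index=0, flank=4)
        assert not motif_matches("TTTT" + "AGGTT", "AGGYV", 0, 4)

    def test_minus_strand_context_is_reverse_complemented(self):
        # forward CCT ending at the site position: read 5'->3' on the minus
        # strand this is AGG, so an AGG-anchored motif matches
        g = m.Genome({"c": "AAAACCTAAA"})
        site = m.MethylationSite("c", 6, "-")
        ctx = site_context(g, site, flank=3)
        assert ctx == "TTTAGGT"
        assert motif_matches(ctx, "AGG", a_index=0, flank=3)

    def test_single_base_motif_is_tautology(self):
        g = m.Genome({"c": "ACGTACGTACGTACGTACGT"})
        sites = make_sites(g, "c", [4, 8, 12], strand="+")
        stats = m.context_stats(sites, g, flank=4, motifs=[("A", 0)])
        assert stats.motif_hits[0].frac_sites_matching == 1.0

    def test_background_recovers_base_composition_under_uniform_sites(self):
        """With sites placed uniformly over adenines, the site flank
        composition matches the genomic background composition."""
        rng = np.random.default_rng(5)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 60_000))
        g = m.Genome({"c": seq})
        arr = g.array("c")
        a_pos = np.nonzero(arr == ord("A"))[0]
        chosen = rng.choice(a_pos[(a_pos > 4) & (a_pos < arr.size - 5)], 3000,
                            replace=False)
        sites = [m.MethylationSite("c", int(p), "+") for p in sorted(chosen)]
        stats = m.context_stats(sites, g, flank=4)
        site_freq = stats.position_counts / stats.position_counts.sum(axis=1, keepdims=True)
        bg_freq = stats.background_counts / stats.background_counts.sum(axis=1, keepdims=True)
        # centre column is pure A in both
        assert site_freq[4, 0] == 1.0 and bg_freq[4, 0] == pytest.approx(1.0)
        assert np.abs(site_freq - bg_freq).max() < 0.05

    def test_invalid_iupac_letter_raises(self, tiny_genome):
        with pytest.raises(ValueError):
            m.context_stats([], tiny_genome, motifs=[("AXG", 0)])
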
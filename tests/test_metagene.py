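"""Metagene profiles: consolidation, smoothing, window orientation, donor
offsets, and the full reverse-complement symmetry property."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import m6amap as m
from conftest import make_sites, revcomp_dataset


class TestConsolidate:
    def test_downsampling_index_formula(self):
        indicator = np.zeros(2000)
        indicator[1] = 1
        out = m.consolidate(indicator, 1000)
        assert out[0] == 1 and out.sum() == 1

    def test_identity_when_lengths_match(self):
        v = np.array([0.0, 1, 0, 1, 1])
        assert (m.consolidate(v, 5) == v).all()

    def test_upsampling_preserves_sum(self):
        indicator = np.zeros(70)
        indicator[[3, 40, 69]] = 1
        out = m.consolidate(indicator, 200)
        assert out.sum() == pytest.approx(3.0, abs=1e-9)

    def test_invalid_grid_raises(self):
        with pytest.raises(ValueError):
            m.consolidate(np.ones(5), 0)

    @settings(max_examples=60, deadline=None)
    @given(
        L=st.integers(1000, 4000),
        grid=st.sampled_from([200, 1000]),
        seed=st.integers(0, 10_000),
    )
    def test_downsampling_matches_naive_remapping(self, L, grid, seed):
        """Uniform sampling equals picking, for each grid point, the base at
        the centre of its bin."""
        rng = np.random.default_rng(seed)
        indicator = (rng.random(L) < 0.01).astype(float)
        out = m.consolidate(indicator, grid)
        naive = np.array(
            [indicator[int((j + 0.5) * L // grid)] for j in range(grid)]
        )
        assert (out == naive).all()


class TestLowess:
    def test_constant_vector_unchanged(self):
        v = np.full(100, 0.3)
        assert m.lowess_smooth(v, 0.05) == pytest.approx(v)

    def test_full_span_reproduces_a_line(self):
        v = np.linspace(0, 1, 50)
        assert m.lowess_smooth(v, f=1.0) == pytest.approx(v, abs=1e-6)

    def test_spike_mass_is_spread(self):
        v = np.zeros(1000)
        v[500] = 1
        out = m.lowess_smooth(v, 0.05)
        assert 0 < out.max() < 1

    def test_invalid_span_raises(self):
        with pytest.raises(ValueError):
            m.lowess_smooth(np.ones(10), 0.0)


class TestGeneBodyProfile:
    def test_fraction_of_genes_at_relative_position(self):
        g = m.Genome({"c": "A" * 5000})
        genes = [
            m.GeneModel.from_exons("g1", "c", "+", [(0, 2000)]),
            m.GeneModel.from_exons("g2", "c", "+", [(3000, 5000)]),
        ]
        # site at the centre of g1 only (base 1001 is the one the central
        # grid point samples for L = 2 * grid)
        sites = make_sites(g, "c", [1001], strand="+")
        prof = m.gene_body_profile(genes, sites)
        assert prof.values[500] == 0.5
        assert prof.values.sum() == 0.5

    def test_minus_strand_site_near_tss_appears_left(self):
        g = m.Genome({"c": "T" * 2000})
        gene = m.GeneModel.from_exons("g", "c", "-", [(0, 2000)])
        # minus-strand TSS is at forward position 1999
        sites = [m.MethylationSite("c", 1990, "-")]
        prof = m.gene_body_profile([gene], sites)
        assert np.argmax(prof.values) < 10

    def test_empty_gene_set_raises(self):
        with pytest.raises(ValueError):
            m.gene_body_profile([], [])


class TestWindowProfile:
    def test_single_anchor_site_at_plus_ten(self):
        g = m.Genome({"c": "A" * 1000})
        sites = make_sites(g, "c", [510], strand="+")
        prof = m.window_profile([("c", 500, "+")], sites, 100, 100, genome=g)
        assert prof.values[100 + 10] == 1.0 and prof.values.sum() == 1.0

    def test_minus_anchor_orientation(self):
        """For a minus-strand anchor, downstream in transcription direction
        is a smaller forward coordinate."""
        g = m.Genome({"c": "T" * 1000})
        sites = [m.MethylationSite("c", 490, "-")]
        prof = m.window_profile([("c", 500, "-")], sites, 100, 100, genome=g)
        assert prof.values[100 + 10] == 1.0

    def test_all_windows_clipped_raises(self):
        g = m.Genome({"c": "A" * 50})
        with pytest.raises(ValueError):
            m.window_profile([("c", 10, "+")], [], 100, 100, genome=g)

    def test_occupancy_values_are_exact_unit_fractions(self, small_dataset):
        ds = small_dataset
        prof = m.window_profile(
            [(g.chrom, g.tts, g.strand) for g in ds.genes], ds.sites, 200, 200,
            genome=ds.genome,
        )
        scaled = prof.values * prof.n_units
        assert np.allclose(scaled, np.round(scaled))


class TestRandomRegions:
    def test_zero_sites_give_zero_profile(self, small_dataset):
        prof = m.random_region_profile(
            [], small_dataset.genome, n_regions=20, length=500, seed=0
        )
        assert prof.values.sum() == 0

    def test_oversized_region_raises(self, small_dataset):
        with pytest.raises(ValueError):
            m.random_region_profile(
                [], small_dataset.genome, 5, 10**7, seed=0
            )


class TestDonorOffsets:
    def test_site_at_last_exonic_base_counts_at_minus_one(self):
        g = m.Genome({"c": "A" * 1000})
        gene = m.GeneModel.from_exons("g", "c", "+", [(0, 300), (400, 700)])
        sites = make_sites(g, "c", [299], strand="+")  # last base of exon 1
        prof = m.donor_offset_profile([gene], sites)
        assert prof.counts[prof.offsets == -1][0] == 1
        assert prof.counts.sum() == 1

    def test_minus_strand_junction_convention(self):
        g = m.Genome({"c": "T" * 1000})
        gene = m.GeneModel.from_exons("g", "c", "-", [(0, 300), (400, 700)])
        # for the minus gene the donor junction of the intron [300,400) has
        # its last exonic base at forward position 400
        sites = [m.MethylationSite("c", 400, "-")]
        prof = m.donor_offset_profile([gene], sites)
        assert prof.counts[prof.offsets == -1][0] == 1

    def test_uniform_placement_gives_flat_enrichment(self):
        rng = np.random.default_rng(0)
        g = m.Genome({"c": "A" * 200_000})
        genes = [
            m.GeneModel.from_exons(
                f"g{i}", "c", "+", [(i * 2000, i * 2000 + 900),
                                    (i * 2000 + 1000, i * 2000 + 1900)]
            )
            for i in range(100)
        ]
        pos = np.sort(rng.choice(200_000, 4000, replace=False))
        sites = make_sites(g, "c", pos, strand="+")
        prof = m.donor_offset_profile(genes, sites)
        assert prof.enrichment.mean() == pytest.approx(1.0)
        assert prof.enrichment.max() < 3.0

    def test_intronless_genes_are_skipped(self):
        gene = m.GeneModel.from_exons("g", "c", "+", [(0, 100)])
        with pytest.raises(ValueError):
            m.donor_offset_profile([gene], [])


class TestStrandSymmetry:
    def test_profiles_invariant_under_reverse_complement(self, small_dataset):
        """Reverse-complementing genome, annotation and sites together leaves
        every profile unchanged."""
        ds = small_dataset
        fg, fgenes, fsites = revcomp_dataset(ds.genome, ds.genes, ds.sites)
        body = m.gene_body_profile(ds.genes, ds.sites)
        fbody = m.gene_body_profile(fgenes, fsites)
        assert np.allclose(body.values, fbody.values)

        tts = m.window_profile(
            [(g.chrom, g.tts, g.strand) for g in ds.genes], ds.sites, 300, 300,
            genome=ds.genome,
        )
        ftts = m.window_profile(
            [(g.chrom, g.tts, g.strand) for g in fgenes], fsites, 300, 300,
            genome=fg,
        )
        assert np.allclose(tts.values, ftts.values)

        donor = m.donor_offset_profile(ds.genes, ds.sites)
        fdonor = m.donor_offset_profile(fgenes, fsites)
        assert (donor.counts == fdonor.counts).all()

    def test_profiles_invariant_under_chromosome_relabeling(self, small_dataset):
        ds = small_dataset
        mapping = {c: f"new_{c}" for c in ds.genome.chrom_ids}
        g2 = m.Genome({mapping[c]: ds.genome.sequence(c) for c in ds.genome.chrom_ids})
        genes2 = [
            m.GeneModel.from_exons(
                g.gene_id, mapping[g.chrom], g.strand, g.exons,
                cds=g.cds, utr5=g.utr5, utr3=g.utr3,
            )
            for g in ds.genes
        ]
        sites2 = [
            m.MethylationSite(mapping[s.chrom], s.pos, s.strand, s.fraction, s.coverage)
            for s in ds.sites
        ]
        p1 = m.gene_body_profile(ds.genes, ds.sites)
        p2 = m.gene_body_profile(genes2, sites2)
        assert np.allclose(p1.values, p2.values)
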
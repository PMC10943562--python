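"""Generator contracts: determinism, realized fractions, null models,
round-trip through the readers, and mutant models."""

import filecmp

import numpy as np
import pytest

import m6amap as m
from m6amap.io_formats import SiteRejectionReport


SMALL = dict(n_chrom=4, chrom_len=60_000, n_genes=60, n_hotspots=2)


class TestDeterminism:
    def test_same_seed_gives_byte_identical_files(self, tmp_path):
        cfg = m.SimulationConfig(seed=5, **SMALL)
        for sub in ("a", "b"):
            ds = m.simulate_dataset(cfg)
            m.write_dataset(ds, tmp_path / sub)
        for name in ("genome.fasta", "genes.gff3", "repeats.gff3", "sites.tsv",
                      "expression.tsv", "degs.tsv", "truth.json",
                      "mutant_sites.tsv"):
            assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name,
                               shallow=False), name

    def test_different_seeds_differ(self):
        a = m.simulate_dataset(m.SimulationConfig(seed=1, **SMALL))
        b = m.simulate_dataset(m.SimulationConfig(seed=2, **SMALL))
        assert a.sites != b.sites


class TestGenomeAnnotation:
    def test_zero_genes_degenerate(self):
        cfg = m.SimulationConfig(seed=0, n_chrom=2, chrom_len=30_000, n_genes=0,
                                 n_hotspots=0)
        genome, genes, repeats = m.simulate_genome_annotation(cfg)
        assert genes == [] and len(repeats) > 0

    def test_realized_te_fraction(self):
        cfg = m.SimulationConfig(seed=3, n_chrom=10, chrom_len=200_000,
                                 n_genes=100, te_fraction=0.1)
        genome, genes, repeats = m.simulate_genome_annotation(cfg)
        te_bp = sum(r.end - r.start for r in repeats if r.repeat_class == "TE")
        assert te_bp / genome.total_length() == pytest.approx(0.1, abs=0.02)

    def test_infeasible_packing_is_hard_error(self):
        cfg = m.SimulationConfig(seed=0, n_chrom=1, chrom_len=20_000, n_genes=50)
        with pytest.raises(ValueError, match="packing"):
            m.simulate_genome_annotation(cfg)

    def test_gene_models_are_internally_consistent(self, small_dataset):
        for g in small_dataset.genes:
            assert g.exons[0][0] == g.start and g.exons[-1][1] == g.end
            for iv in list(g.cds) + list(g.utr5) + list(g.utr3):
                assert any(s <= iv[0] and iv[1] <= e for s, e in g.exons)


class TestMethylome:
    def test_null_model_site_count(self):
        """With all multipliers at 1 and no hotspots, the realized count is
        binomial around base_rate x #adenines."""
        cfg = m.SimulationConfig(
            seed=9, n_chrom=5, chrom_len=100_000, n_genes=50,
            motif_factor=1.0, body_gradient=(1.0, 1.0), tts_peak=(1.0, 150.0),
            donor_bump=1.0, te_factor=1.0, n_hotspots=0,
        )
        genome, genes, repeats = m.simulate_genome_annotation(cfg)
        sites, truth = m.simulate_methylome(genome, genes, repeats, cfg)
        total_a = sum(
            int((genome.array(c) == ord("A")).sum() + (genome.array(c) == ord("T")).sum())
            for c in genome.chrom_ids
        )
        expected = cfg.base_rate * total_a
        assert abs(len(sites) - expected) <= 3 * np.sqrt(expected)

    def test_fractions_in_declared_range(self, small_dataset):
        assert all(0.1 <= s.fraction <= 0.8 for s in small_dataset.sites)

    def test_planted_hotspots_satisfy_call_definition(self, small_dataset):
        ds = small_dataset
        called = m.call_hotspots(ds.sites)
        for chrom, start, end in ds.truth.hotspot_intervals:
            best = max(
                (
                    min(end, h.end) - max(start, h.start)
                    for h in called
                    if h.chrom == chrom
                ),
                default=0,
            )
            assert best > 0, "planted hotspot not recovered"

    def test_written_files_reparse_with_zero_rejections(self, small_dataset, tmp_path):
        ds = small_dataset
        paths = m.write_dataset(ds, tmp_path)
        genome = m.read_genome(paths["genome"])
        report = SiteRejectionReport()
        sites = m.read_methylation_sites(paths["sites_tsv"], genome, report=report)
        assert report.n_non_adenine == 0
        assert len(sites) == len(ds.sites)
        genes = m.read_gene_models(paths["genes"])
        assert len(genes) == len(ds.genes)
        assert {g.gene_id for g in genes} == {g.gene_id for g in ds.genes}
        repeats = m.read_repeats(paths["repeats"])
        assert len(repeats) == len(ds.repeats)


class TestExpression:
    def test_tpm_nonnegative(self, small_dataset):
        for rec in small_dataset.expression:
            assert all(t >= 0 for t in rec.tpm_replicates)
            assert rec.tpm_mean == pytest.approx(np.mean(rec.tpm_replicates))

    def test_slope_zero_decouples(self):
        cfg = m.SimulationConfig(seed=2, expr_slope=0.0, **SMALL)
        genome, genes, repeats = m.simulate_genome_annotation(cfg)
        sites, truth = m.simulate_methylome(genome, genes, repeats, cfg)
        expr = m.simulate_expression(genes, truth.per_gene_body_count, cfg)
        tpm = {e.gene_id: e.tpm_mean for e in expr}
        plus = [tpm[g] for g, c in truth.per_gene_body_count.items() if c > 0]
        minus = [tpm[g] for g, c in truth.per_gene_body_count.items() if c == 0]
        res = m.compare_groups(plus, minus)
        assert res.p_value > 0.01  # no coupling at this seed


class TestMutants:
    def test_neutral_mutant_matches_wt(self):
        cfg = m.SimulationConfig(seed=4, mutant_model={"demethylase_ko": 1.0},
                                 **SMALL)
        ds = m.simulate_dataset(cfg)
        assert len(ds.mutant_sites) == len(ds.sites)

    def test_demethylase_ko_adds_sites_on_top_of_wt(self, small_dataset):
        wt_keys = {(s.chrom, s.pos, s.strand) for s in small_dataset.sites}
        mut_keys = {(s.chrom, s.pos, s.strand) for s in small_dataset.mutant_sites}
        assert wt_keys <= mut_keys
        assert len(mut_keys) > len(wt_keys)

    def test_full_methylase_ko_empties_every_marked_gene(self):
        cfg = m.SimulationConfig(seed=6, mutant_model={"methylase_ko": 1.0},
                                 **SMALL)
        genome, genes, repeats = m.simulate_genome_annotation(cfg)
        sites, truth = m.simulate_methylome(genome, genes, repeats, cfg)
        cfg2 = m.SimulationConfig(seed=6, mutant_model={"methylase_ko": 1.0},
                                  replicate_retention=1.0, **SMALL)
        wt_reps, mut_reps, mutant_base = m.simulate_mutant(
            sites, genome, genes, repeats, cfg2
        )
        records, _ = m.gene_level_diff(wt_reps, mut_reps, genes, genome)
        for r in records:
            if r.marked_all_wt:
                assert r.state_change == "to_none"

    def test_replicates_are_subsets_of_their_base(self, small_dataset):
        base = set(map(id, []))  # noqa: F841 (clarity below)
        wt_keys = {(s.chrom, s.pos, s.strand) for s in small_dataset.sites}
        for rep in small_dataset.wt_replicates:
            rep_keys = {(s.chrom, s.pos, s.strand) for s in rep.sites}
            assert rep_keys <= wt_keys
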
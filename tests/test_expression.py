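"""Methylation-expression association: gene summaries, TPM bins, rank-sum
comparisons and the class expression table."""

import itertools

import numpy as np
import pytest

import m6amap as m
from conftest import make_sites


@pytest.fixture
def toy():
    """One 10-kb chromosome with a single plus-strand two-exon gene at
    [4000, 6000) and its promoter at [2000, 4000)."""
    genome = m.Genome({"c": "A" * 10_000})
    gene = m.GeneModel.from_exons(
        "g1", "c", "+", [(4000, 4800), (5200, 6000)],
        cds=[(4100, 4800), (5200, 5900)],
        utr5=[(4000, 4100)], utr3=[(5900, 6000)],
    )
    return genome, gene


class TestGeneSummaries:
    def summarize(self, genome, gene, sites, **kw):
        return m.summarize_gene_methylation([gene], sites, genome, **kw)["g1"]

    def test_promoter_only_site_classifies_promoter(self, toy):
        genome, gene = toy
        s = self.summarize(genome, gene, make_sites(genome, "c", [3000], "+"))
        assert s.promoter_body_class == "Promoter"
        assert not s.gene_plus

    def test_tss_window_boundary_inclusive(self, toy):
        genome, gene = toy
        # transcription-oriented offset -300 from the TSS at 4000
        s = self.summarize(genome, gene, make_sites(genome, "c", [3700], "+"))
        assert s.tss_plus

    def test_utr3_site_implies_gene_plus(self, toy):
        genome, gene = toy
        s = self.summarize(genome, gene, make_sites(genome, "c", [5950], "+"))
        assert s.utr3_plus and s.gene_plus
        assert s.promoter_body_class == "Body"

    def test_opposite_strand_site_ignored_under_gene_strand_policy(self, toy):
        genome, gene = toy
        sites = [m.MethylationSite("c", 5000, "-")]  # not adenine-checked here
        s = self.summarize(genome, gene, sites)
        assert not s.gene_plus
        s2 = self.summarize(genome, gene, sites, strand_policy="both")
        assert s2.gene_plus

    def test_class_membership_partitions_genes(self, default_dataset):
        ds = default_dataset
        summaries = m.summarize_gene_methylation(ds.genes, ds.sites, ds.genome)
        counts = {"None": 0, "Promoter": 0, "Body": 0, "Both": 0}
        for s in summaries.values():
            counts[s.promoter_body_class] += 1
        assert sum(counts.values()) == len(summaries) == len(ds.genes)


class TestTpmBins:
    def _summaries(self, flags):
        out = {}
        for i, gene_plus in enumerate(flags):
            out[f"g{i}"] = m.expression.GeneMethylationSummary(
                gene_id=f"g{i}", body_count=int(gene_plus), body_adenines=100,
                promoter_count=0, tss_window_count=0, tts_window_count=0,
                cds_count=0, intron_count=0, utr5_count=0, utr3_count=0,
                te_count=0,
            )
        return out

    def _expr(self, tpms):
        return [m.ExpressionRecord(f"g{i}", (t,), t) for i, t in enumerate(tpms)]

    def test_low_bin_fractions(self):
        table, _ = m.tpm_bin_fractions(
            self._summaries([False, False, True, True]),
            self._expr([0.5, 0.9, 0.5, 20.0]),
        )
        assert table["Gene-"][0] == 1.0
        assert table["Gene+"] == [0.5, 0, 0, 0.5]

    def test_rows_sum_to_one(self):
        table, _ = m.tpm_bin_fractions(
            self._summaries([True, False, True]), self._expr([2.0, 2.0, 2.0])
        )
        for fr in table.values():
            if fr is not None:
                assert sum(fr) == pytest.approx(1.0)
                assert fr[1] == 1.0  # everything in the 1-5 bin


class TestCompareGroups:
    def test_exact_one_sided_p_is_one_twentieth(self):
        res = m.compare_groups([10, 20, 30], [1, 2, 3], alternative="a_greater")
        assert res.p_value == pytest.approx(0.05)
        assert res.direction == "a>b"

    def test_identical_groups(self):
        res = m.compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == 1.0 and res.direction == "none"

    def test_clear_shift_is_significant(self):
        a = [float(i) + 100 for i in range(1, 21)]
        b = [float(i) for i in range(1, 21)]
        res = m.compare_groups(a, b)
        assert res.p_value < 0.01 and res.direction == "a>b"

    def test_exact_branch_matches_full_enumeration(self):
        """p(one-sided) equals the fraction of labelings with U >= observed
        over all C(n_a+n_b, n_a) relabelings."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            n_a = int(rng.integers(1, 6))
            n_b = int(rng.integers(1, 10 - n_a + 1))
            pooled = rng.random(n_a + n_b)
            a, b = pooled[:n_a], pooled[n_a:]

            def u_stat(x, y):
                return sum((xi > yi) for xi in x for yi in y)

            obs = u_stat(a, b)
            count = 0
            total = 0
            for idx in itertools.combinations(range(n_a + n_b), n_a):
                sel = np.zeros(n_a + n_b, dtype=bool)
                sel[list(idx)] = True
                total += 1
                if u_stat(pooled[sel], pooled[~sel]) >= obs:
                    count += 1
            res = m.compare_groups(a, b, alternative="a_greater")
            assert res.p_value == pytest.approx(count / total, abs=1e-12)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            m.compare_groups([], [1.0])


class TestOccupancyByExpression:
    def _setup(self, counts_high, counts_low):
        genome = m.Genome({"c": "A" * 100_000})
        genes, expr, sites = [], [], []
        pos = 0
        for i, (count, tpm) in enumerate(
            [(c, 200.0) for c in counts_high] + [(c, 5.0) for c in counts_low]
        ):
            g = m.GeneModel.from_exons(f"g{i}", "c", "+", [(pos, pos + 1000)])
            genes.append(g)
            expr.append(m.ExpressionRecord(f"g{i}", (tpm,), tpm))
            sites += make_sites(genome, "c", range(pos + 10, pos + 10 + 20 * count, 20), "+")
            pos += 1500
        return genes, sites, expr

    def test_identical_strata_ratio_zero(self):
        genes, sites, expr = self._setup([1, 1], [1, 1])
        _, _, ratio, _ = m.occupancy_by_expression(genes, sites, expr)
        assert ratio == pytest.approx(0.0)

    def test_two_vs_one_sites_per_gene_ratio_one(self):
        genes, sites, expr = self._setup([2, 2], [1, 1])
        _, _, ratio, _ = m.occupancy_by_expression(genes, sites, expr)
        assert ratio == pytest.approx(1.0)

    def test_empty_stratum_raises(self):
        genes, sites, expr = self._setup([1], [])
        with pytest.raises(ValueError):
            m.occupancy_by_expression(genes, sites, expr)


class TestClassExpressionTable:
    def test_all_unmethylated_yields_single_class(self, toy):
        genome, gene = toy
        summaries = m.summarize_gene_methylation([gene], [], genome)
        expr = [m.ExpressionRecord("g1", (2.0,), 2.0)]
        teg = m.assign_tegs([gene], [], scope="gene_body")
        mean_tpm, comparisons = m.class_expression_table(summaries, expr, teg)
        assert list(mean_tpm) == [("non-TEG", "None")]
        assert [c for c in comparisons if "None" in c.group_a] == []

    def test_te_marked_tegs_compare_against_unmarked(self):
        """TE+ genes given low TPM, TE- high: direction b>a with exact p."""
        genome = m.Genome({"c": "A" * 50_000})
        genes, tes, sites, expr = [], [], [], []
        for i in range(8):
            start = i * 5000 + 2500
            g = m.GeneModel.from_exons(f"g{i}", "c", "+", [(start, start + 1000)])
            genes.append(g)
            tes.append(m.RepeatFeature("c", start + 100, start + 300, "TE",
                                       "DNA/CMC-EnSpm", f"TE_{i + 1}"))
            te_marked = i < 4
            if te_marked:
                sites += make_sites(genome, "c", [start + 150], "+")
            tpm = 1.5 + 0.1 * i if te_marked else 15.0 + i
            expr.append(m.ExpressionRecord(f"g{i}", (tpm,), tpm))
        teg = m.assign_tegs(genes, tes, scope="gene_body")
        summaries = m.summarize_gene_methylation(
            genes, sites, genome, repeats=tes, teg=teg
        )
        _, comparisons = m.class_expression_table(summaries, expr, teg)
        te_cmp = [c for c in comparisons if c.group_a == "TE+"][0]
        assert te_cmp.direction == "b>a"
        assert te_cmp.p_value == pytest.approx(1 / 70 * 2, rel=1e-6)  # exact two-sided
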
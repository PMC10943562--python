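"""Shared fixtures: hand-built micro-genomes and the default synthetic
dataset (session-scoped; every generator stage runs once)."""

from __future__ import annotations

import numpy as np
import pytest

import m6amap as m


@pytest.fixture(scope="session")
def default_dataset() -> m.simulate.SyntheticDataset:
    """The default-scale synthetic dataset (20 x 100 kb, 600 genes), seed 1."""
    return m.simulate_dataset(m.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def small_dataset() -> m.simulate.SyntheticDataset:
    """A small dataset for structural / symmetry checks."""
    return m.simulate_dataset(
        m.SimulationConfig(seed=7, n_chrom=4, chrom_len=60_000, n_genes=60,
                           n_hotspots=2)
    )


@pytest.fixture
def tiny_genome() -> m.Genome:
    # chr1: A at positions 7 and 12 (+ strand), T at position 3 (- strand A)
    return m.Genome({"chr1": "CCCTCCCAGGCAAGTCCCCC", "chr2": "ACGTACGTACGTACGTACGT"})


def brute_force_hotspots(positions, min_sites=10, gap_max=100):
    """Independent O(n^2) oracle: enumerate every window of sorted positions,
    keep those whose internal gaps are all < gap_max, with >= min_sites
    sites, and which cannot be extended either way."""
    pos = sorted(positions)
    n = len(pos)
    runs = []
    for i in range(n):
        for j in range(i, n):
            ok = all(pos[k + 1] - pos[k] < gap_max for k in range(i, j))
            if not ok or j - i + 1 < min_sites:
                continue
            left_max = i == 0 or pos[i] - pos[i - 1] >= gap_max
            right_max = j == n - 1 or pos[j + 1] - pos[j] >= gap_max
            if left_max and right_max:
                runs.append((pos[i], pos[j] + 1, j - i + 1))
    return sorted(set(runs))


def make_sites(genome: m.Genome, chrom: str, positions, strand=None):
    """MethylationSite list from forward positions, inferring the strand from
    the genome base (A -> +, T -> -) unless given."""
    arr = genome.array(chrom)
    out = []
    for p in positions:
        st = strand
        if st is None:
            st = "+" if arr[p] == ord("A") else "-"
        out.append(m.MethylationSite(chrom, int(p), st))
    return out


def revcomp_dataset(genome: m.Genome, genes, sites):
    """Reverse-complement the genome and mirror annotation + sites; used for
    the strand-symmetry property."""
    comp = str.maketrans("ACGTN", "TGCAN")
    flipped_genome = m.Genome(
        {c: genome.sequence(c).translate(comp)[::-1] for c in genome.chrom_ids}
    )

    def flip_iv(chrom, iv):
        L = genome.length(chrom)
        return (L - iv[1], L - iv[0])

    flipped_genes = []
    for g in genes:
        flipped_genes.append(
            m.GeneModel.from_exons(
                gene_id=g.gene_id,
                chrom=g.chrom,
                strand="-" if g.strand == "+" else "+",
                exons=[flip_iv(g.chrom, iv) for iv in g.exons],
                cds=[flip_iv(g.chrom, iv) for iv in g.cds],
                utr5=[flip_iv(g.chrom, iv) for iv in g.utr5],
                utr3=[flip_iv(g.chrom, iv) for iv in g.utr3],
            )
        )
    flipped_sites = [
        m.MethylationSite(
            s.chrom,
            genome.length(s.chrom) - 1 - s.pos,
            "-" if s.strand == "+" else "+",
            s.fraction,
            s.coverage,
        )
        for s in sites
    ]
    return flipped_genome, flipped_genes, flipped_sites
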
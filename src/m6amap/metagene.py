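"""Positional 6mA occupancy profiles.

Consolidated gene-body and intron profiles (each unit remapped to a fixed
grid: 1000 points for gene bodies, 200 for introns), fixed windows around
TSS/TTS/TE anchors, random-region baselines, and splice-donor offset
enrichment. Occupancy at a grid point / offset is the fraction of units
(genes, anchors) carrying a site there; profiles can be smoothed with
LOWESS (span f = 0.05, zero robustifying iterations), matching how such
metagene curves are conventionally drawn.

Orientation: all per-gene axes run 5'->3' in transcription direction, so a
minus-strand gene is flipped before consolidation and window offsets are
positive downstream of the anchor in transcription direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .annotation import GeneModel
from .io_formats import Genome, MethylationSite, sites_by_chrom


@dataclass
class MetageneProfile:
    grid_length: int
    values: np.ndarray
    n_units: int
    smoothing: str = "none"  # "none" or "lowess(f)"

    def smoothed(self, f: float = 0.05) -> "MetageneProfile":
        return MetageneProfile(
            grid_length=self.grid_length,
            values=lowess_smooth(self.values, f=f),
            n_units=self.n_units,
            smoothing=f"lowess({f:g})",
        )


@dataclass
class DonorOffsetProfile:
    """6mA counts at transcription-oriented offsets around exon|intron
    junctions: offset -1 is the last exonic base, +1 the first intronic
    base (offset 0 does not exist)."""

    w: int
    offsets: np.ndarray  # [-w..-1, +1..+w]
    counts: np.ndarray
    n_junctions: int

    @property
    def enrichment(self) -> np.ndarray:
        mean = self.counts.mean()
        if mean == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / mean


def consolidate(indicator: np.ndarray, grid: int) -> np.ndarray:
    """Remap a length-L binary (or real) vector to a fixed-length grid.

    For L >= grid, uniform sampling: out[j] = indicator[floor((j+0.5)*L/grid)].
    For L < grid, each original base is spread to its two nearest grid points
    by linear interpolation so the vector sum is preserved.
    """
    if grid <= 0:
        raise ValueError("grid must be positive")
    x = np.asarray(indicator, dtype=float)
    L = x.size
    if L < 1:
        raise ValueError("indicator must have length >= 1")
    if L >= grid:
        idx = np.floor((np.arange(grid) + 0.5) * L / grid).astype(np.int64)
        return x[idx]
    out = np.zeros(grid)
    # centre of base i on the grid axis
    centres = (np.arange(L) + 0.5) * grid / L - 0.5
    lo = np.floor(centres).astype(np.int64)
    frac = centres - lo
    for i in range(L):
        if x[i] == 0:
            continue
        j, f = lo[i], frac[i]
        if j < 0:
            out[0] += x[i]
        elif j >= grid - 1:
            out[grid - 1] += x[i]
        else:
            out[j] += x[i] * (1 - f)
            out[j + 1] += x[i] * f
    return out


def lowess_smooth(values: np.ndarray, f: float = 0.05) -> np.ndarray:
    """LOWESS with span ``f`` and no robustifying iterations; same length."""
    if not 0 < f <= 1:
        raise ValueError("f must be in (0, 1]")
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("need at least 3 values to smooth")
    x = np.arange(values.size, dtype=float)
    return _sm_lowess(values, x, frac=f, it=0, return_sorted=False)


def _gene_strand_positions(
    gene: GeneModel, grouped: dict[str, tuple[np.ndarray, np.ndarray]]
) -> np.ndarray:
    """Forward-strand positions of sites on the gene's strand within its span."""
    if gene.chrom not in grouped:
        return np.array([], dtype=np.int64)
    pos, plus = grouped[gene.chrom]
    lo, hi = np.searchsorted(pos, [gene.start, gene.end])
    sel = plus[lo:hi] if gene.strand == "+" else ~plus[lo:hi]
    return pos[lo:hi][sel]


def gene_body_profile(
    genes: Sequence[GeneModel],
    sites: Sequence[MethylationSite],
    grid: int = 1000,
    smooth_f: float | None = None,
) -> MetageneProfile:
    """Mean consolidated gene-body indicator across genes (strand-specific).

    Each gene contributes a binary vector over its body on its own 5'->3'
    axis; the profile value at a grid point is the fraction of genes with a
    site at that relative position."""
    if not genes:
        raise ValueError("empty gene set")
    grouped = sites_by_chrom(sites)
    acc = np.zeros(grid)
    for g in genes:
        indicator = np.zeros(g.length)
        p = _gene_strand_positions(g, grouped)
        indicator[p - g.start] = 1.0
        if g.strand == "-":
            indicator = indicator[::-1]
        acc += consolidate(indicator, grid)
    profile = MetageneProfile(grid, acc / len(genes), len(genes))
    if smooth_f is not None:
        profile = profile.smoothed(smooth_f)
    return profile


def intron_profile(
    genes: Sequence[GeneModel],
    sites: Sequence[MethylationSite],
    grid: int = 200,
    smooth_f: float | None = None,
) -> MetageneProfile:
    """Consolidated intron profile (200-point grid); intron strand is the
    strand of the host gene."""
    grouped = sites_by_chrom(sites)
    acc = np.zeros(grid)
    n = 0
    for g in genes:
        for s, e in g.introns:
            indicator = np.zeros(e - s)
            if g.chrom in grouped:
                pos, plus = grouped[g.chrom]
                lo, hi = np.searchsorted(pos, [s, e])
                sel = plus[lo:hi] if g.strand == "+" else ~plus[lo:hi]
                indicator[pos[lo:hi][sel] - s] = 1.0
            if g.strand == "-":
                indicator = indicator[::-1]
            acc += consolidate(indicator, grid)
            n += 1
    if n == 0:
        raise ValueError("no introns in gene set")
    profile = MetageneProfile(grid, acc / n, n)
    if smooth_f is not None:
        profile = profile.smoothed(smooth_f)
    return profile


def window_profile(
    anchors: Sequence[tuple[str, int, str]],
    sites: Sequence[MethylationSite],
    upstream: int,
    downstream: int,
    genome: Genome | None = None,
    strand_specific: bool = True,
) -> MetageneProfile:
    """Occupancy at transcription-oriented offsets around point anchors.

    Offsets run from -upstream to +downstream (positive = downstream in
    transcription direction; for a minus-strand anchor that is a smaller
    forward coordinate). Windows extending past a chromosome edge are
    dropped and counted out of ``n_units``.
    """
    grouped = sites_by_chrom(sites)
    width = upstream + downstream + 1
    acc = np.zeros(width)
    used = 0
    for chrom, pos0, strand in anchors:
        if strand == "+":
            lo, hi = pos0 - upstream, pos0 + downstream + 1
        else:
            lo, hi = pos0 - downstream, pos0 + upstream + 1
        if genome is not None and (lo < 0 or hi > genome.length(chrom)):
            continue
        used += 1
        if chrom not in grouped:
            continue
        pos, plus = grouped[chrom]
        a, b = np.searchsorted(pos, [max(lo, 0), hi])
        seg_pos = pos[a:b]
        seg_plus = plus[a:b]
        if strand_specific:
            sel = seg_plus if strand == "+" else ~seg_plus
            seg_pos = seg_pos[sel]
        offsets = (seg_pos - pos0) if strand == "+" else (pos0 - seg_pos)
        acc_idx = offsets + upstream
        ok = (acc_idx >= 0) & (acc_idx < width)
        np.add.at(acc, acc_idx[ok], 1.0)
    if used == 0:
        raise ValueError("all windows clipped")
    return MetageneProfile(width, acc / used, used)


def random_region_profile(
    sites: Sequence[MethylationSite],
    genome: Genome,
    n_regions: int,
    length: int,
    seed: int = 0,
    upstream: int | None = None,
    downstream: int | None = None,
) -> MetageneProfile:
    """Occupancy around the centres of uniform random same-length regions;
    the baseline paired with TE window profiles."""
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    min_len = min(genome.lengths.values())
    if length > min_len:
        raise ValueError("region length exceeds shortest chromosome")
    up = length // 2 if upstream is None else upstream
    down = length // 2 if downstream is None else downstream
    rng = np.random.default_rng(seed)
    chrom_ids = genome.chrom_ids
    weights = np.array([genome.length(c) - length + 1 for c in chrom_ids], dtype=float)
    weights /= weights.sum()
    anchors = []
    while len(anchors) < n_regions:
        chrom = chrom_ids[rng.choice(len(chrom_ids), p=weights)]
        start = int(rng.integers(0, genome.length(chrom) - length + 1))
        centre = start + length // 2
        if centre - up >= 0 and centre + down + 1 <= genome.length(chrom):
            anchors.append((chrom, centre, "+"))
    return window_profile(
        anchors, sites, up, down, genome=genome, strand_specific=False
    )


def donor_offset_profile(
    genes: Sequence[GeneModel],
    sites: Sequence[MethylationSite],
    w: int = 10,
) -> DonorOffsetProfile:
    """Count sites at offsets -w..-1 (exonic) and +1..+w (intronic) around
    every splice-donor junction, on the host gene's strand."""
    grouped = sites_by_chrom(sites)
    offsets = np.concatenate([np.arange(-w, 0), np.arange(1, w + 1)])
    counts = np.zeros(offsets.size, dtype=np.int64)
    n_junctions = 0
    for g in genes:
        if not g.introns:
            continue
        if g.chrom in grouped:
            pos, plus = grouped[g.chrom]
            strand_sel = plus if g.strand == "+" else ~plus
            gpos = pos[strand_sel]
        else:
            gpos = np.array([], dtype=np.int64)
        for s, e in g.introns:
            n_junctions += 1
            # forward coordinate of the last exonic base before the donor
            if g.strand == "+":
                # exon ends at s (half-open): offset -1 is position s-1,
                # +1 is position s (first intronic base)
                lo, hi = s - w, s + w
                a, b = np.searchsorted(gpos, [lo, hi])
                off = gpos[a:b] - s
                off = np.where(off >= 0, off + 1, off)  # skip nonexistent 0
            else:
                # donor junction is at the intron's right edge: last exonic
                # base is e, first intronic base is e-1 (transcription runs
                # right to left)
                lo, hi = e - w, e + w
                a, b = np.searchsorted(gpos, [lo, hi])
                off = e - 1 - gpos[a:b]
                off = np.where(off >= 0, off + 1, off)
            idx = np.where(off < 0, off + w, off + w - 1)
            ok = (idx >= 0) & (idx < offsets.size)
            np.add.at(counts, idx[ok], 1)
    if n_junctions == 0:
        raise ValueError("no introns in gene set")
    return DonorOffsetProfile(w=w, offsets=offsets, counts=counts, n_junctions=n_junctions)
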
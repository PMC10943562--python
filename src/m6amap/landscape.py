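"""Genome-wide 6mA landscape statistics.

Per-feature-class methylation statistics (fragment-methylated proportion and
6mA/A density), the inter-site interval distribution, hotspot calling
(maximal runs of >=10 sites with adjacent gaps <100 bp), a permutation test
for hotspot association with transposable elements, and sequence-context
statistics around sites (flank base composition plus IUPAC motif
enrichment, AGGYV-style).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .annotation import FeatureClassSet, count_adenines
from .io_formats import Genome, MethylationSite, RepeatFeature, sites_by_chrom

IUPAC = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

DEFAULT_MOTIFS = (("AGGYV", 0), ("GAGG", 1))


# ---------------------------------------------------------------------------
# per-class statistics
# ---------------------------------------------------------------------------


@dataclass
class FeatureClassStats:
    class_name: str
    n_fragments: int
    n_fragments_methylated: int
    n_adenines: int
    n_6ma: int

    @property
    def frac_fragments_methylated(self) -> float | None:
        return (
            self.n_fragments_methylated / self.n_fragments if self.n_fragments else None
        )

    @property
    def density_6ma_per_a(self) -> float | None:
        return self.n_6ma / self.n_adenines if self.n_adenines else None


def feature_methylation_stats(
    sites: Sequence[MethylationSite],
    classes: dict[str, FeatureClassSet],
    genome: Genome,
    strand_specific: bool = True,
) -> dict[str, FeatureClassStats]:
    """Fragment-methylated proportion and 6mA/A density per feature class.

    Stranded classes count only sites on the feature strand and only the
    adenines of that strand; unstranded classes (Intergenic, repeats) pool
    both strands. ``strand_specific=False`` forces pooling everywhere.
    """
    grouped = sites_by_chrom(sites)
    out: dict[str, FeatureClassStats] = {}
    for name, fcs in classes.items():
        n_a = n_m = 0
        meth_units: set[str] = set()
        units: set[str] = set()
        for iv in fcs.intervals:
            units.add(iv.unit_id)
            strand = iv.strand if (strand_specific and fcs.stranded) else None
            n_a += count_adenines(genome, iv.chrom, iv.start, iv.end, strand)
            if iv.chrom in grouped:
                pos, plus = grouped[iv.chrom]
                lo, hi = np.searchsorted(pos, [iv.start, iv.end])
                if strand == "+":
                    k = int(plus[lo:hi].sum())
                elif strand == "-":
                    k = int((~plus[lo:hi]).sum())
                else:
                    k = int(hi - lo)
                n_m += k
                if k:
                    meth_units.add(iv.unit_id)
        out[name] = FeatureClassStats(
            class_name=name,
            n_fragments=len(units),
            n_fragments_methylated=len(meth_units),
            n_adenines=n_a,
            n_6ma=n_m,
        )
    return out


def compare_proportions(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Pooled two-proportion z-test; returns (z, two-sided p).

    z = (p1 - p2) / sqrt(p(1-p)(1/n1 + 1/n2)) with p the pooled proportion.
    """
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("k must satisfy 0 <= k <= n")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("n must be positive")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return 0.0, 1.0
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (p1 - p2) / se
    return z, 2 * stats.norm.sf(abs(z))


# ---------------------------------------------------------------------------
# inter-site intervals
# ---------------------------------------------------------------------------


@dataclass
class GapDistribution:
    """Distances between adjacent sites, pooled across strands, never across
    chromosomes."""

    gaps_by_chrom: dict[str, np.ndarray]

    @property
    def all_gaps(self) -> np.ndarray:
        arrays = [g for g in self.gaps_by_chrom.values() if g.size]
        return np.concatenate(arrays) if arrays else np.array([], dtype=np.int64)

    def fraction_below(self, threshold: int) -> float | None:
        gaps = self.all_gaps
        if gaps.size == 0:
            return None
        return float((gaps < threshold).mean())


def intersite_intervals(sites: Sequence[MethylationSite]) -> GapDistribution:
    grouped = sites_by_chrom(sites)
    gaps = {
        chrom: np.diff(pos) if pos.size > 1 else np.array([], dtype=np.int64)
        for chrom, (pos, _plus) in grouped.items()
    }
    return GapDistribution(gaps)


# ---------------------------------------------------------------------------
# hotspots
# ---------------------------------------------------------------------------


@dataclass
class HotspotCall:
    chrom: str
    start: int
    end: int  # half-open: last member site position + 1
    n_sites: int
    max_gap: int
    overlaps_te: bool | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


def call_hotspots(
    sites: Sequence[MethylationSite],
    min_sites: int = 10,
    gap_max: int = 100,
    stranded: bool = False,
) -> list[HotspotCall]:
    """Maximal runs of >= ``min_sites`` sites whose adjacent gaps are all
    strictly < ``gap_max`` bp. Strands are pooled by default (hotspots are
    treated as genomic regions); ``stranded=True`` scans each strand
    separately."""
    grouped = sites_by_chrom(sites)
    out: list[HotspotCall] = []
    for chrom in sorted(grouped):
        pos, plus = grouped[chrom]
        streams = [pos[plus], pos[~plus]] if stranded else [pos]
        for p in streams:
            if p.size == 0:
                continue
            # split where the gap rule breaks; every remaining run is maximal
            breaks = np.nonzero(np.diff(p) >= gap_max)[0] + 1
            for run in np.split(p, breaks):
                if run.size >= min_sites:
                    gaps = np.diff(run)
                    out.append(
                        HotspotCall(
                            chrom=chrom,
                            start=int(run[0]),
                            end=int(run[-1]) + 1,
                            n_sites=int(run.size),
                            max_gap=int(gaps.max()) if gaps.size else 0,
                        )
                    )
    out.sort(key=lambda h: (h.chrom, h.start))
    return out


@dataclass
class PermutationResult:
    observed_fraction: float
    null_mean: float
    null_sd: float
    p_value: float
    n_perm: int
    seed: int


def _interval_overlap_fraction(
    intervals: list[tuple[str, int, int]],
    merged_tes: dict[str, tuple[np.ndarray, np.ndarray]],
) -> float:
    hit = 0
    for chrom, start, end in intervals:
        if chrom not in merged_tes:
            continue
        starts, ends = merged_tes[chrom]
        i = np.searchsorted(ends, start, side="right")
        if i < starts.size and starts[i] < end:
            hit += 1
    return hit / len(intervals)


def _merge_te_intervals(
    repeats: Sequence[RepeatFeature],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in repeats:
        if r.repeat_class == "TE":
            by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    merged = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        acc = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= acc[-1][1]:
                acc[-1][1] = max(acc[-1][1], e)
            else:
                acc.append([s, e])
        merged[chrom] = (
            np.array([s for s, _ in acc], dtype=np.int64),
            np.array([e for _, e in acc], dtype=np.int64),
        )
    return merged


def hotspot_te_permutation(
    hotspots: Sequence[HotspotCall],
    repeats: Sequence[RepeatFeature],
    genome: Genome,
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Permutation test of hotspot/TE association.

    The observed statistic is the fraction of hotspots overlapping >=1 TE by
    >=1 bp. Each permutation relocates every hotspot to a uniform random
    start on its own chromosome, preserving its length (relocated hotspots
    may overlap each other). One-sided empirical p with add-one correction:
    p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    if not hotspots:
        raise ValueError("need at least one hotspot")
    merged = _merge_te_intervals(repeats)
    obs_iv = [(h.chrom, h.start, h.end) for h in hotspots]
    observed = _interval_overlap_fraction(obs_iv, merged)
    for h in hotspots:
        if h.length > genome.length(h.chrom):
            raise ValueError(f"hotspot longer than chromosome {h.chrom}")
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    lengths = {h: genome.length(h) for h in genome.chrom_ids}
    for i in range(n_perm):
        perm = []
        for h in hotspots:
            lo_max = lengths[h.chrom] - h.length
            s = int(rng.integers(0, lo_max + 1))
            perm.append((h.chrom, s, s + h.length))
        null[i] = _interval_overlap_fraction(perm, merged)
    p = (1 + int((null >= observed).sum())) / (n_perm + 1)
    return PermutationResult(
        observed_fraction=observed,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)) if n_perm > 1 else 0.0,
        p_value=p,
        n_perm=n_perm,
        seed=seed,
    )


def annotate_hotspot_te_overlap(
    hotspots: Sequence[HotspotCall], repeats: Sequence[RepeatFeature]
) -> None:
    merged = _merge_te_intervals(repeats)
    for h in hotspots:
        h.overlaps_te = (
            _interval_overlap_fraction([(h.chrom, h.start, h.end)], merged) > 0
            if merged
            else False
        )


# ---------------------------------------------------------------------------
# sequence context
# ---------------------------------------------------------------------------


@dataclass
class MotifHit:
    motif: str
    a_index: int
    n_sites_matching: int
    frac_sites_matching: float
    background_frac: float

    @property
    def enrichment(self) -> float | None:
        if self.background_frac == 0:
            return None
        return self.frac_sites_matching / self.background_frac


@dataclass
class ContextStats:
    flank: int
    n_sites_used: int
    n_sites_skipped: int
    position_counts: np.ndarray  # (2*flank+1, 4) counts over A,C,G,T
    background_counts: np.ndarray
    motif_hits: list[MotifHit] = field(default_factory=list)


_CODE = {65: 0, 67: 1, 71: 2, 84: 3}  # A C G T
_COMP_ARR = np.zeros(256, dtype=np.uint8)
for a, b in zip(b"ACGTN", b"TGCAN"):
    _COMP_ARR[a] = b


def _revcomp_arr(arr: np.ndarray) -> np.ndarray:
    return _COMP_ARR[arr[::-1]]


def _iupac_mask(ch: str) -> np.ndarray:
    """Boolean lookup over ASCII codes for one IUPAC letter."""
    if ch not in IUPAC:
        raise ValueError(f"invalid IUPAC letter {ch!r}")
    mask = np.zeros(256, dtype=bool)
    for b in IUPAC[ch]:
        mask[ord(b)] = True
    return mask


def motif_matches(context: str, motif: str, a_index: int, flank: int) -> bool:
    """Does the motif, anchored with its adenine at ``a_index``, match the
    (2*flank+1)-mer context whose centre is the site?"""
    start = flank - a_index
    if start < 0 or start + len(motif) > len(context):
        raise ValueError("motif does not fit in context window")
    window = context[start : start + len(motif)]
    return all(b in IUPAC[m] for b, m in zip(window, motif))


def _background_motif_frac(genome: Genome, motif: str, a_index: int) -> float:
    """Fraction of all genomic adenines (both strands) whose context matches
    the motif at its anchor."""
    masks = [_iupac_mask(c) for c in motif]
    total = 0
    matched = 0
    for chrom in genome.chrom_ids:
        arr = genome.array(chrom)
        n = arr.size
        for strand_arr in (arr, _revcomp_arr(arr)):
            is_a = strand_arr == ord("A")
            total += int(is_a.sum())
            ok = is_a.copy()
            # motif position j sits at offset (j - a_index) from the adenine
            for j, mask in enumerate(masks):
                off = j - a_index
                shifted = np.zeros(n, dtype=bool)
                if off >= 0:
                    shifted[: n - off] = mask[strand_arr[off:]]
                else:
                    shifted[-off:] = mask[strand_arr[: n + off]]
                ok &= shifted
            matched += int(ok.sum())
    return matched / total if total else 0.0


def site_context(
    genome: Genome, site: MethylationSite, flank: int
) -> str | None:
    """The (2*flank+1)-mer read 5'->3' on the site strand, or None when the
    site is closer than ``flank`` to a chromosome edge."""
    arr = genome.array(site.chrom)
    if site.pos - flank < 0 or site.pos + flank + 1 > arr.size:
        return None
    window = arr[site.pos - flank : site.pos + flank + 1]
    if site.strand == "-":
        window = _revcomp_arr(window)
    return window.tobytes().decode("ascii")


def context_stats(
    sites: Sequence[MethylationSite],
    genome: Genome,
    flank: int = 4,
    motifs: Sequence[tuple[str, int]] = DEFAULT_MOTIFS,
) -> ContextStats:
    """Flank base-composition matrix and IUPAC motif enrichment around sites.

    Contexts are read 5'->3' on the site strand; the background is the base
    composition (and motif match fraction) over all genomic adenine contexts
    on both strands.
    """
    for motif, _ in motifs:
        for ch in motif:
            if ch not in IUPAC:
                raise ValueError(f"invalid IUPAC letter {ch!r} in motif {motif}")
    width = 2 * flank + 1
    counts = np.zeros((width, 4), dtype=np.int64)
    contexts: list[str] = []
    skipped = 0
    for s in sites:
        ctx = site_context(genome, s, flank)
        if ctx is None or "N" in ctx:
            skipped += 1
            continue
        contexts.append(ctx)
        for i, b in enumerate(ctx):
            counts[i, _CODE[ord(b)]] += 1

    background = np.zeros((width, 4), dtype=np.int64)
    for chrom in genome.chrom_ids:
        arr = genome.array(chrom)
        n = arr.size
        for strand_arr in (arr, _revcomp_arr(arr)):
            is_a = strand_arr == ord("A")
            for off in range(-flank, flank + 1):
                row = off + flank
                if off >= 0:
                    center = is_a[: n - off] if off else is_a
                    basecol = strand_arr[off:]
                else:
                    center = is_a[-off:]
                    basecol = strand_arr[: n + off]
                for code, col in _CODE.items():
                    background[row, col] += int((basecol[center] == code).sum())

    hits = []
    n_used = len(contexts)
    for motif, a_index in motifs:
        k = sum(motif_matches(ctx, motif, a_index, flank) for ctx in contexts)
        hits.append(
            MotifHit(
                motif=motif,
                a_index=a_index,
                n_sites_matching=k,
                frac_sites_matching=k / n_used if n_used else 0.0,
                background_frac=_background_motif_frac(genome, motif, a_index),
            )
        )
    return ContextStats(
        flank=flank,
        n_sites_used=n_used,
        n_sites_skipped=skipped,
        position_counts=counts,
        background_counts=background,
        motif_hits=hits,
    )
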
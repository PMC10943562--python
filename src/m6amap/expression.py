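"""Methylation-expression association.

Per-gene methylation summaries (body, promoter, TSS/TTS windows, CDS,
intron, UTRs, overlapping TEs), TPM-bin composition of methylation classes,
rank-sum comparisons of expression between classes, the high-vs-low
expression occupancy contrast, and the promoter/body methylation-class
expression table split by TE association.

Windows follow the figure conventions of the study design: the TSS window
is transcription-oriented [-300, +100] (inclusive on both ends), the TTS
window +/-500; "active" genes have TPM > 1 and "highly expressed" TPM > 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import GeneModel, TegAssignment, count_adenines
from .io_formats import (
    ExpressionRecord,
    Genome,
    MethylationSite,
    RepeatFeature,
    sites_by_chrom,
)
from .metagene import MetageneProfile, gene_body_profile

TPM_BINS = ((0.0, 1.0), (1.0, 5.0), (5.0, 10.0), (10.0, float("inf")))
TPM_BIN_LABELS = ("<=1", "1-5", "5-10", ">=10")


@dataclass
class GeneMethylationSummary:
    gene_id: str
    body_count: int
    body_adenines: int
    promoter_count: int
    tss_window_count: int
    tts_window_count: int
    cds_count: int
    intron_count: int
    utr5_count: int
    utr3_count: int
    te_count: int  # sites inside TEs overlapping this gene (TEGs only; else 0)

    @property
    def body_density(self) -> float | None:
        return self.body_count / self.body_adenines if self.body_adenines else None

    @property
    def gene_plus(self) -> bool:
        return self.body_count >= 1

    @property
    def tss_plus(self) -> bool:
        return self.tss_window_count >= 1

    @property
    def tts_plus(self) -> bool:
        return self.tts_window_count >= 1

    @property
    def utr3_plus(self) -> bool:
        return self.utr3_count >= 1

    @property
    def te_plus(self) -> bool:
        return self.te_count >= 1

    @property
    def promoter_body_class(self) -> str:
        prom, body = self.promoter_count >= 1, self.gene_plus
        if prom and body:
            return "Both"
        if prom:
            return "Promoter"
        if body:
            return "Body"
        return "None"


def _count_in(
    grouped, chrom: str, start: int, end: int, strand: str | None
) -> int:
    """Sites in [start, end) on the given strand (None = both)."""
    if chrom not in grouped or start >= end:
        return 0
    pos, plus = grouped[chrom]
    lo, hi = np.searchsorted(pos, [max(start, 0), end])
    if strand == "+":
        return int(plus[lo:hi].sum())
    if strand == "-":
        return int((~plus[lo:hi]).sum())
    return int(hi - lo)


def summarize_gene_methylation(
    genes: Sequence[GeneModel],
    sites: Sequence[MethylationSite],
    genome: Genome,
    repeats: Sequence[RepeatFeature] = (),
    teg: Sequence[TegAssignment] = (),
    promoter_len: int = 2000,
    tss_window: tuple[int, int] = (300, 100),
    tts_window: int = 500,
    strand_policy: str = "gene_strand",
) -> dict[str, GeneMethylationSummary]:
    """Per-gene 6mA counts and window flags.

    ``strand_policy='gene_strand'`` counts only sites on the gene's strand
    (TE-overlap counts always pool strands, repeats being unstranded);
    ``'both'`` pools strands everywhere. Windows are clipped at chromosome
    edges; boundaries inclusive on both ends.
    """
    if strand_policy not in ("gene_strand", "both"):
        raise ValueError(f"unknown strand policy {strand_policy!r}")
    grouped = sites_by_chrom(sites)
    te_by_gene: dict[str, list[tuple[str, int, int]]] = {}
    if teg:
        te_index = {
            (r.repeat_id or f"TE_{i + 1}"): r
            for i, r in enumerate(repeats)
            if r.repeat_class == "TE"
        }
        for a in teg:
            te_by_gene[a.gene_id] = [
                (te_index[t].chrom, te_index[t].start, te_index[t].end)
                for t in a.te_ids_overlapping
                if t in te_index
            ]
    out = {}
    for g in genes:
        strand = g.strand if strand_policy == "gene_strand" else None
        clen = genome.length(g.chrom)
        up, down = tss_window
        if g.strand == "+":
            tss_iv = (g.tss - up, g.tss + down + 1)
            tts_iv = (g.tts - tts_window, g.tts + tts_window + 1)
        else:
            tss_iv = (g.tss - down, g.tss + up + 1)
            tts_iv = (g.tts - tts_window, g.tts + tts_window + 1)
        tss_iv = (max(0, tss_iv[0]), min(clen, tss_iv[1]))
        tts_iv = (max(0, tts_iv[0]), min(clen, tts_iv[1]))
        prom = g.promoter(promoter_len, clen)
        te_count = sum(
            _count_in(grouped, c, s, e, None) for c, s, e in te_by_gene.get(g.gene_id, [])
        )
        out[g.gene_id] = GeneMethylationSummary(
            gene_id=g.gene_id,
            body_count=_count_in(grouped, g.chrom, g.start, g.end, strand),
            body_adenines=count_adenines(
                genome, g.chrom, g.start, g.end, strand
            ),
            promoter_count=(
                _count_in(grouped, g.chrom, prom[0], prom[1], strand) if prom else 0
            ),
            tss_window_count=_count_in(grouped, g.chrom, tss_iv[0], tss_iv[1], strand),
            tts_window_count=_count_in(grouped, g.chrom, tts_iv[0], tts_iv[1], strand),
            cds_count=sum(
                _count_in(grouped, g.chrom, s, e, strand) for s, e in g.cds
            ),
            intron_count=sum(
                _count_in(grouped, g.chrom, s, e, strand) for s, e in g.introns
            ),
            utr5_count=sum(
                _count_in(grouped, g.chrom, s, e, strand) for s, e in g.utr5
            ),
            utr3_count=sum(
                _count_in(grouped, g.chrom, s, e, strand) for s, e in g.utr3
            ),
            te_count=te_count,
        )
    return out


def tpm_bin_fractions(
    summaries: dict[str, GeneMethylationSummary],
    expression: Sequence[ExpressionRecord],
    bins: Sequence[tuple[float, float]] = TPM_BINS,
):
    """Fraction of each methylation class falling in each TPM bin.

    Bin edges: [0, 1], (1, 5], (5, 10], (10, inf). Classes are the paired
    flags Gene+/Gene-, TSS+/TSS-, TTS+/TTS-. Returns (table, n_unmatched)
    where table maps class -> list of per-bin fractions (rows sum to 1).
    """
    tpm = {e.gene_id: e.tpm_mean for e in expression}
    classes: dict[str, list[float]] = {
        name: []
        for name in ("Gene+", "Gene-", "TSS+", "TSS-", "TTS+", "TTS-")
    }
    unmatched = 0
    for gid, s in summaries.items():
        if gid not in tpm:
            unmatched += 1
            continue
        t = tpm[gid]
        classes["Gene+" if s.gene_plus else "Gene-"].append(t)
        classes["TSS+" if s.tss_plus else "TSS-"].append(t)
        classes["TTS+" if s.tts_plus else "TTS-"].append(t)

    def bin_index(t: float) -> int:
        if t <= bins[0][1]:
            return 0
        for i, (lo, hi) in enumerate(bins[1:], start=1):
            if lo < t <= hi:
                return i
        return len(bins) - 1

    table: dict[str, list[float] | None] = {}
    for name, values in classes.items():
        if not values:
            table[name] = None
            continue
        counts = [0] * len(bins)
        for t in values:
            counts[bin_index(t)] += 1
        table[name] = [c / len(values) for c in counts]
    return table, unmatched


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    statistic: float
    p_value: float
    direction: str  # a>b, b>a or none
    p_adjusted: float | None = None


def compare_groups(
    tpm_a: Sequence[float],
    tpm_b: Sequence[float],
    alternative: str = "two_sided",
    group_a: str = "a",
    group_b: str = "b",
) -> GroupComparison:
    """Mann-Whitney rank-sum comparison of two samples.

    Exact null distribution when min(n) <= 8 and there are no ties; normal
    approximation with tie correction otherwise.
    """
    a = np.asarray(tpm_a, dtype=float)
    b = np.asarray(tpm_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")
    no_ties = np.unique(np.concatenate([a, b])).size == a.size + b.size
    method = "exact" if (min(a.size, b.size) <= 8 and no_ties) else "asymptotic"
    alt = {"two_sided": "two-sided", "a_greater": "greater"}[alternative]
    res = stats.mannwhitneyu(a, b, alternative=alt, method=method)
    u = float(res.statistic)
    mid = a.size * b.size / 2
    direction = "none" if u == mid else ("a>b" if u > mid else "b>a")
    return GroupComparison(
        group_a=group_a,
        group_b=group_b,
        n_a=int(a.size),
        n_b=int(b.size),
        statistic=u,
        p_value=float(min(res.pvalue, 1.0)),
        direction=direction,
    )


def occupancy_by_expression(
    genes: Sequence[GeneModel],
    sites: Sequence[MethylationSite],
    expression: Sequence[ExpressionRecord],
    threshold: float = 100.0,
    grid: int = 1000,
) -> tuple[MetageneProfile, MetageneProfile, float, GroupComparison]:
    """Gene-body profiles for highly expressed (TPM > threshold) vs low
    (TPM <= threshold) genes, the relative excess of mean per-gene body site
    count in the high stratum, and a rank-sum test on the per-gene counts."""
    tpm = {e.gene_id: e.tpm_mean for e in expression}
    high = [g for g in genes if tpm.get(g.gene_id, 0.0) > threshold]
    low = [g for g in genes if g.gene_id in tpm and tpm[g.gene_id] <= threshold]
    if not high or not low:
        raise ValueError("empty expression stratum")
    grouped = sites_by_chrom(sites)

    def body_counts(gs):
        return [
            _count_in(grouped, g.chrom, g.start, g.end, g.strand) for g in gs
        ]

    c_high, c_low = body_counts(high), body_counts(low)
    ratio = float(np.mean(c_high)) / float(np.mean(c_low)) - 1 if np.mean(c_low) else float("inf")
    cmp = compare_groups(
        c_high, c_low, alternative="a_greater", group_a="High", group_b="Low"
    )
    return (
        gene_body_profile(high, sites, grid=grid),
        gene_body_profile(low, sites, grid=grid),
        ratio,
        cmp,
    )


def class_expression_table(
    summaries: dict[str, GeneMethylationSummary],
    expression: Sequence[ExpressionRecord],
    teg: Sequence[TegAssignment],
    active_tpm: float = 1.0,
):
    """The promoter/body/TE/3'UTR expression contrasts.

    Returns (mean_tpm_table, comparisons): per (TEG|non-TEG) x
    {None, Promoter, Body, Both} mean TPM with pairwise rank-sum tests
    against the None class, plus TE+ vs TE- among active TEGs and
    UTR3+ vs UTR3- among active genes. Benjamini-Hochberg adjusted p-values
    are reported alongside the raw ones across the whole comparison family.
    """
    tpm = {e.gene_id: e.tpm_mean for e in expression}
    is_teg = {a.gene_id: a.is_teg for a in teg}
    mean_tpm: dict[tuple[str, str], tuple[int, float]] = {}
    groups: dict[tuple[str, str], list[float]] = {}
    for gid, s in summaries.items():
        if gid not in tpm:
            continue
        side = "TEG" if is_teg.get(gid, False) else "non-TEG"
        groups.setdefault((side, s.promoter_body_class), []).append(tpm[gid])
    for key, vals in groups.items():
        mean_tpm[key] = (len(vals), float(np.mean(vals)))

    comparisons: list[GroupComparison] = []
    for side in ("TEG", "non-TEG"):
        none_vals = groups.get((side, "None"), [])
        for cls in ("Promoter", "Body", "Both"):
            vals = groups.get((side, cls), [])
            if not vals or not none_vals:
                continue
            comparisons.append(
                compare_groups(
                    vals,
                    none_vals,
                    group_a=f"{side}:{cls}",
                    group_b=f"{side}:None",
                )
            )
    # TE+ vs TE- among active TEGs
    te_pos, te_neg = [], []
    utr_pos, utr_neg = [], []
    for gid, s in summaries.items():
        t = tpm.get(gid)
        if t is None or t <= active_tpm:
            continue
        if is_teg.get(gid, False):
            (te_pos if s.te_plus else te_neg).append(t)
        (utr_pos if s.utr3_plus else utr_neg).append(t)
    if te_pos and te_neg:
        comparisons.append(
            compare_groups(te_pos, te_neg, group_a="TE+", group_b="TE-")
        )
    if utr_pos and utr_neg:
        comparisons.append(
            compare_groups(utr_pos, utr_neg, group_a="UTR3+", group_b="UTR3-")
        )
    if comparisons:
        adj = multipletests([c.p_value for c in comparisons], method="fdr_bh")[1]
        for c, p in zip(comparisons, adj):
            c.p_adjusted = float(p)
    return mean_tpm, comparisons
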
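"""Wild-type vs mutant differential methylation.

Global 6mA/A shift between genotypes (with a one-tailed rank-sum test on
per-chromosome densities), replicate-consistent gene marking, per-gene
fold-change and methylation-state-change categories, and the cross-tab of
6mA dynamics against differentially expressed genes.

A gene counts as *marked* in a genotype only when it carries >=1 gene-body
site in every replicate of that genotype; its 6mA *level* is the gene-body
6mA/A density on the gene strand, averaged over replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .annotation import GeneModel, count_adenines
from .io_formats import DegRecord, Genome, MethylationSite, sites_by_chrom


@dataclass
class SampleMethylome:
    sample_id: str
    genotype: str  # WT or mutant
    replicate: str
    sites: list[MethylationSite]
    _genome: Genome

    @property
    def global_density(self) -> float:
        total_a = sum(
            count_adenines(self._genome, c, 0, self._genome.length(c), None)
            for c in self._genome.chrom_ids
        )
        return len(self.sites) / total_a

    @property
    def per_chrom_density(self) -> dict[str, float]:
        grouped = sites_by_chrom(self.sites)
        out = {}
        for c in self._genome.chrom_ids:
            n_a = count_adenines(self._genome, c, 0, self._genome.length(c), None)
            n = grouped[c][0].size if c in grouped else 0
            out[c] = n / n_a if n_a else 0.0
        return out


def global_shift(
    wt: Sequence[SampleMethylome],
    mut: Sequence[SampleMethylome],
    unit: str = "chromosome",
) -> tuple[float, float]:
    """Percent change of global 6mA/A in the mutant and a one-tailed
    rank-sum p-value (mutant > WT).

    ``unit='chromosome'`` pools per-chromosome densities across replicates
    as test units (the default: with two replicates per genotype a rank-sum
    on whole samples cannot resolve p < 0.05); ``unit='sample'`` uses the
    per-sample global densities.
    """
    if not wt or not mut:
        raise ValueError("need >=1 sample per genotype")
    wt_global = np.array([s.global_density for s in wt])
    mut_global = np.array([s.global_density for s in mut])
    if wt_global.mean() == 0:
        raise ValueError("zero WT density")
    percent_change = (mut_global.mean() / wt_global.mean() - 1) * 100
    if unit == "chromosome":
        a = np.concatenate([list(s.per_chrom_density.values()) for s in mut])
        b = np.concatenate([list(s.per_chrom_density.values()) for s in wt])
    elif unit == "sample":
        a, b = mut_global, wt_global
    else:
        raise ValueError(f"unknown unit {unit!r}")
    p = float(stats.mannwhitneyu(a, b, alternative="greater").pvalue)
    return float(percent_change), p


@dataclass
class DiffMethRecord:
    gene_id: str
    marked_all_wt: bool
    marked_all_mut: bool
    level_wt: float
    level_mut: float

    @property
    def shared(self) -> bool:
        return self.marked_all_wt and self.marked_all_mut

    @property
    def fold_change(self) -> float | None:
        if self.level_wt > 0:
            return self.level_mut / self.level_wt
        return None

    def fc_category(self, fc_up: float = 2.0, fc_down: float = 0.5) -> str:
        fc = self.fold_change
        if fc is None:
            return "na"
        if fc > fc_up:
            return "up"
        if fc < fc_down:
            return "down"
        return "stable"

    @property
    def state_change(self) -> str:
        if self.marked_all_wt and self.marked_all_mut:
            return "stable_marked"
        if self.marked_all_wt:
            return "to_none"
        if self.marked_all_mut:
            return "from_none"
        return "never"


@dataclass
class DiffMethSummary:
    n_union: int  # genes marked in every replicate of >=1 genotype
    frac_shared: float
    frac_shared_fc_changed: float  # among shared genes: |fc| beyond thresholds
    frac_shared_fc_up: float
    frac_to_none: float  # over the union
    frac_from_none: float


def gene_level_diff(
    wt: Sequence[SampleMethylome],
    mut: Sequence[SampleMethylome],
    genes: Sequence[GeneModel],
    genome: Genome,
    fc_up: float = 2.0,
    fc_down: float = 0.5,
) -> tuple[list[DiffMethRecord], DiffMethSummary]:
    """Replicate-consistent per-gene marking and 6mA-level comparison.

    Returns records for the *union* of genes marked (in all replicates) in
    at least one genotype, plus the summary fractions: shared genes, shared
    genes with fold change beyond thresholds, increased share, and
    state-change fractions over the union.
    """
    if not wt or not mut:
        raise ValueError("need >=1 replicate per genotype")

    def per_gene(sample: SampleMethylome):
        grouped = sites_by_chrom(sample.sites)
        counts = {}
        for g in genes:
            if g.chrom in grouped:
                pos, plus = grouped[g.chrom]
                lo, hi = np.searchsorted(pos, [g.start, g.end])
                sel = plus[lo:hi] if g.strand == "+" else ~plus[lo:hi]
                counts[g.gene_id] = int(sel.sum())
            else:
                counts[g.gene_id] = 0
        return counts

    body_a = {
        g.gene_id: count_adenines(genome, g.chrom, g.start, g.end, g.strand)
        for g in genes
    }
    wt_counts = [per_gene(s) for s in wt]
    mut_counts = [per_gene(s) for s in mut]
    records = []
    for g in genes:
        gid = g.gene_id
        n_a = body_a[gid] or 1
        marked_wt = all(c[gid] >= 1 for c in wt_counts)
        marked_mut = all(c[gid] >= 1 for c in mut_counts)
        if not (marked_wt or marked_mut):
            continue
        records.append(
            DiffMethRecord(
                gene_id=gid,
                marked_all_wt=marked_wt,
                marked_all_mut=marked_mut,
                level_wt=float(np.mean([c[gid] for c in wt_counts])) / n_a,
                level_mut=float(np.mean([c[gid] for c in mut_counts])) / n_a,
            )
        )
    n_union = len(records)
    shared = [r for r in records if r.shared]
    fc_cats = [r.fc_category(fc_up, fc_down) for r in shared]
    n_changed = sum(c in ("up", "down") for c in fc_cats)
    summary = DiffMethSummary(
        n_union=n_union,
        frac_shared=len(shared) / n_union if n_union else 0.0,
        frac_shared_fc_changed=n_changed / len(shared) if shared else 0.0,
        frac_shared_fc_up=(
            sum(c == "up" for c in fc_cats) / len(shared) if shared else 0.0
        ),
        frac_to_none=(
            sum(r.state_change == "to_none" for r in records) / n_union
            if n_union
            else 0.0
        ),
        frac_from_none=(
            sum(r.state_change == "from_none" for r in records) / n_union
            if n_union
            else 0.0
        ),
    )
    return records, summary


@dataclass
class DegOverlay:
    """Cross-tab of DEG direction vs 6mA fold-change category."""

    counts: dict[tuple[str, str], int] = field(default_factory=dict)
    n_degs_without_record: int = 0

    def cell(self, deg_direction: str, fc_category: str) -> int:
        return self.counts.get((deg_direction, fc_category), 0)


def overlay_deg(
    records: Sequence[DiffMethRecord],
    degs: Sequence[DegRecord],
    fc_up: float = 2.0,
    fc_down: float = 0.5,
) -> DegOverlay:
    """Cross-tabulate DEG direction (up/down) against 6mA fold-change
    category (up / down / stable); DEGs without a diffmeth record or with
    undefined fold change are excluded and counted."""
    by_gene = {r.gene_id: r for r in records}
    overlay = DegOverlay()
    for d in degs:
        r = by_gene.get(d.gene_id)
        if r is None or r.fold_change is None:
            overlay.n_degs_without_record += 1
            continue
        key = (d.direction, r.fc_category(fc_up, fc_down))
        overlay.counts[key] = overlay.counts.get(key, 0) + 1
    return overlay
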
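"""Category-level enrichment statistics.

Binomial enrichment of methylated genes per functional category (COG-style),
with Benjamini-Hochberg adjustment; the gene-length vs methylated-fraction
Pearson correlation across categories; a Grubbs outlier screen on per-category
6mA densities; and binomial tests of DEG ratios in gene subsets against the
genome-wide ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import GeneModel
from .expression import GeneMethylationSummary


def binomial_enrichment(
    k: int, n: int, p0: float, alternative: str = "greater"
) -> float:
    """Exact binomial tail probability of seeing k successes in n trials at
    success probability p0."""
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    alt = {"greater": "greater", "two_sided": "two-sided"}[alternative]
    return float(stats.binomtest(k, n, p0, alternative=alt).pvalue)


@dataclass
class CategoryEnrichment:
    category: str
    n_genes: int
    n_methylated: int
    background_frac: float
    p_raw: float
    p_adjusted: float | None
    mean_gene_length: float
    density: float | None  # pooled 6mA/A over the category's gene bodies

    @property
    def frac(self) -> float:
        return self.n_methylated / self.n_genes


@dataclass
class GrubbsResult:
    g_statistic: float
    critical_value: float
    outlier_index: int

    @property
    def has_outlier(self) -> bool:
        return self.g_statistic > self.critical_value


def grubbs_test(values: Sequence[float], alpha: float = 0.05) -> GrubbsResult:
    """Two-sided Grubbs test for a single outlier.

    G = max|x - mean| / s (sample SD); the critical value at level alpha
    comes from the t-distribution with n-2 degrees of freedom.
    """
    n = len(values)
    if n < 3:
        raise ValueError("Grubbs test needs at least 3 values")
    mean = sum(values) / n
    s = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
    if s == 0:
        raise ValueError("zero variance")
    devs = [abs(v - mean) for v in values]
    g = max(devs) / s
    t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
    crit = (n - 1) / math.sqrt(n) * math.sqrt(t**2 / (n - 2 + t**2))
    return GrubbsResult(
        g_statistic=g, critical_value=float(crit), outlier_index=devs.index(max(devs))
    )


@dataclass
class CogTableResult:
    categories: list[CategoryEnrichment]
    length_frac_pearson_r: float | None
    length_frac_pearson_p: float | None
    density_grubbs: GrubbsResult | None


def cog_table(
    summaries: dict[str, GeneMethylationSummary],
    cog_map: dict[str, str],
    genes: Sequence[GeneModel] = (),
    alternative: str = "greater",
) -> CogTableResult:
    """Per-category methylation enrichment against the all-annotated-genes
    background, plus the cross-category length/fraction correlation and the
    density outlier screen."""
    lengths = {g.gene_id: g.length for g in genes}
    by_cat: dict[str, list[str]] = {}
    for gid, cat in cog_map.items():
        if gid in summaries:
            by_cat.setdefault(cat, []).append(gid)
    if not by_cat:
        raise ValueError("cog_map covers no summarized gene")
    all_ids = [gid for ids in by_cat.values() for gid in ids]
    background = sum(summaries[g].gene_plus for g in all_ids) / len(all_ids)
    cats = []
    for cat, ids in sorted(by_cat.items()):
        k = sum(summaries[g].gene_plus for g in ids)
        n = len(ids)
        if 0 < background < 1:
            p_raw = binomial_enrichment(k, n, background, alternative)
        else:
            p_raw = 1.0
        total_sites = sum(summaries[g].body_count for g in ids)
        total_a = sum(summaries[g].body_adenines for g in ids)
        cats.append(
            CategoryEnrichment(
                category=cat,
                n_genes=n,
                n_methylated=k,
                background_frac=background,
                p_raw=p_raw,
                p_adjusted=None,
                mean_gene_length=(
                    sum(lengths.get(g, 0) for g in ids) / n if lengths else float("nan")
                ),
                density=total_sites / total_a if total_a else None,
            )
        )
    adj = multipletests([c.p_raw for c in cats], method="fdr_bh")[1]
    for c, p in zip(cats, adj):
        c.p_adjusted = float(p)

    r = p = None
    xs = [c.mean_gene_length for c in cats]
    ys = [c.frac for c in cats]
    if len(cats) >= 3 and len(set(xs)) > 1 and len(set(ys)) > 1:
        res = stats.pearsonr(xs, ys)
        r, p = float(res.statistic), float(res.pvalue)
    dens = [c.density for c in cats if c.density is not None]
    grubbs = None
    if len(dens) >= 3 and len(set(dens)) > 1:
        grubbs = grubbs_test(dens)
    return CogTableResult(
        categories=cats,
        length_frac_pearson_r=r,
        length_frac_pearson_p=p,
        density_grubbs=grubbs,
    )


def deg_ratio_test(
    k_sub: int, n_sub: int, k_all: int, n_all: int
) -> tuple[float, float, float]:
    """Binomial test of a subset's DEG ratio against the overall ratio.

    Returns (p_value, subset_fraction, overall_fraction); one-sided greater.
    """
    if n_sub <= 0:
        raise ValueError("empty subset")
    if not 0 < k_all < n_all:
        raise ValueError("overall ratio must be in (0, 1)")
    p0 = k_all / n_all
    return binomial_enrichment(k_sub, n_sub, p0, "greater"), k_sub / n_sub, p0
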
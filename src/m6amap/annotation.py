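"""Strand-aware feature geography of the genome.

Builds the per-class interval sets used by the landscape statistics
(gene bodies, 2-kb promoters, exons, introns, CDS, UTRs, intergenic space,
repeat classes) and the gene <-> transposable-element association ("TEG"
labeling). Classes are deliberately non-exclusive: a base can belong to a
gene body, a CDS and a TE at the same time, and each class is later scored
independently.

Conventions: intervals are 0-based half-open on the forward strand. The
promoter is the ``promoter_len`` bases immediately 5' of the TSS on the gene
strand, clipped at chromosome edges. ``Genes*`` is gene body plus promoter;
``Intergenic`` is the unstranded genome complement of Genes*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_formats import Genome, RepeatFeature

logger = logging.getLogger(__name__)

Interval = tuple[int, int]


@dataclass(frozen=True)
class GeneModel:
    """A gene with one transcript model.

    ``tss``/``tts`` are 0-based positions of the first and last transcribed
    base in transcription order (so on the minus strand ``tss > tts``).
    Introns are the inter-exon gaps; UTRs and CDS are subsets of the exons.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[Interval, ...]
    introns: tuple[Interval, ...]
    cds: tuple[Interval, ...]
    utr5: tuple[Interval, ...]
    utr3: tuple[Interval, ...]
    tss: int
    tts: int

    @classmethod
    def from_exons(
        cls,
        gene_id: str,
        chrom: str,
        strand: str,
        exons: Sequence[Interval],
        cds: Sequence[Interval] = (),
        utr5: Sequence[Interval] = (),
        utr3: Sequence[Interval] = (),
    ) -> "GeneModel":
        if strand not in ("+", "-"):
            raise ValueError(f"invalid strand {strand!r} for gene {gene_id}")
        exons = tuple(sorted(tuple(iv) for iv in exons))
        if not exons:
            raise ValueError(f"gene {gene_id} has no exons")
        for (s, e) in exons:
            if not s < e:
                raise ValueError(f"gene {gene_id} has an empty exon")
        introns = tuple(
            (e1, s2) for (_s1, e1), (s2, _e2) in zip(exons, exons[1:]) if e1 < s2
        )
        start, end = exons[0][0], exons[-1][1]
        tss, tts = (start, end - 1) if strand == "+" else (end - 1, start)
        return cls(
            gene_id=gene_id,
            chrom=chrom,
            strand=strand,
            start=start,
            end=end,
            exons=exons,
            introns=introns,
            cds=tuple(sorted(tuple(iv) for iv in cds)),
            utr5=tuple(sorted(tuple(iv) for iv in utr5)),
            utr3=tuple(sorted(tuple(iv) for iv in utr3)),
            tss=tss,
            tts=tts,
        )

    @property
    def length(self) -> int:
        return self.end - self.start

    def promoter(self, promoter_len: int, chrom_len: int) -> Interval | None:
        """Promoter interval on the gene strand, clipped at chromosome edges.
        Returns None when clipping leaves nothing."""
        if self.strand == "+":
            s, e = self.start - promoter_len, self.start
        else:
            s, e = self.end, self.end + promoter_len
        s, e = max(0, s), min(chrom_len, e)
        if s >= e:
            logger.info("promoter of %s fully clipped", self.gene_id)
            return None
        return (s, e)


@dataclass(frozen=True)
class ClassInterval:
    chrom: str
    start: int
    end: int
    strand: str | None  # None for unstranded classes
    unit_id: str  # the feature (gene / repeat / promoter) this fragment belongs to


@dataclass
class FeatureClassSet:
    """All intervals of one genomic feature class.

    ``stranded`` classes are scored on the feature strand only; unstranded
    classes (Intergenic and the repeat classes) pool both strands. Several
    intervals may share a ``unit_id`` (e.g. the exons of one gene): a *unit*
    is the fragment to which the fragment-methylated rule applies.
    """

    class_name: str
    intervals: list[ClassInterval] = field(default_factory=list)
    stranded: bool = True

    @property
    def unit_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for iv in self.intervals:
            seen.setdefault(iv.unit_id, None)
        return list(seen)


def _merge_intervals(ivs: list[Interval]) -> list[Interval]:
    if not ivs:
        return []
    ivs = sorted(ivs)
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _complement(ivs: list[Interval], length: int) -> list[Interval]:
    out = []
    cur = 0
    for s, e in _merge_intervals(ivs):
        if cur < s:
            out.append((cur, s))
        cur = max(cur, e)
    if cur < length:
        out.append((cur, length))
    return out


def build_feature_sets(
    genes: Sequence[GeneModel],
    repeats: Sequence[RepeatFeature],
    genome: Genome,
    promoter_len: int = 2000,
) -> dict[str, FeatureClassSet]:
    """Build the per-class interval sets of the feature geography.

    Returns a dict keyed by class name: Genes, Genes*, Promoter, Exon,
    Intron, CDS, UTR5, UTR3, Intergenic, TE, SR, LC, TEG, TEG*.
    TEG/TEG* are filled by :func:`assign_tegs` scope; here they are the
    gene-body / Genes* intervals of genes overlapping >=1 TE.
    """
    if promoter_len <= 0:
        raise ValueError("promoter_len must be positive")
    classes: dict[str, FeatureClassSet] = {
        name: FeatureClassSet(name)
        for name in (
            "Genes",
            "Genes*",
            "Promoter",
            "Exon",
            "Intron",
            "CDS",
            "UTR5",
            "UTR3",
        )
    }
    genes_star_by_chrom: dict[str, list[Interval]] = {c: [] for c in genome.chrom_ids}
    for g in genes:
        clen = genome.length(g.chrom)
        classes["Genes"].intervals.append(
            ClassInterval(g.chrom, g.start, g.end, g.strand, g.gene_id)
        )
        prom = g.promoter(promoter_len, clen)
        star = [(g.start, g.end)]
        if prom is not None:
            classes["Promoter"].intervals.append(
                ClassInterval(g.chrom, prom[0], prom[1], g.strand, g.gene_id)
            )
            star.append(prom)
        star = _merge_intervals(star)
        for s, e in star:
            classes["Genes*"].intervals.append(
                ClassInterval(g.chrom, s, e, g.strand, g.gene_id)
            )
            genes_star_by_chrom[g.chrom].append((s, e))
        for cname, ivs in (
            ("Exon", g.exons),
            ("Intron", g.introns),
            ("CDS", g.cds),
            ("UTR5", g.utr5),
            ("UTR3", g.utr3),
        ):
            for s, e in ivs:
                classes[cname].intervals.append(
                    ClassInterval(g.chrom, s, e, g.strand, g.gene_id)
                )

    intergenic = FeatureClassSet("Intergenic", stranded=False)
    for chrom in genome.chrom_ids:
        for i, (s, e) in enumerate(
            _complement(genes_star_by_chrom[chrom], genome.length(chrom))
        ):
            intergenic.intervals.append(
                ClassInterval(chrom, s, e, None, f"{chrom}_intergenic_{i + 1}")
            )
    classes["Intergenic"] = intergenic

    for rclass in ("TE", "SR", "LC"):
        fcs = FeatureClassSet(rclass, stranded=False)
        for i, r in enumerate(repeats):
            if r.repeat_class == rclass:
                fcs.intervals.append(
                    ClassInterval(
                        r.chrom, r.start, r.end, None, r.repeat_id or f"{rclass}_{i + 1}"
                    )
                )
        classes[rclass] = fcs

    # TEG classes from Genes* scope (the Fig-1E-style definition)
    teg = assign_tegs(genes, repeats, scope="genes_star", promoter_len=promoter_len, genome=genome)
    teg_ids = {a.gene_id for a in teg if a.is_teg}
    for src, name in (("Genes", "TEG"), ("Genes*", "TEG*")):
        fcs = FeatureClassSet(name, stranded=True)
        fcs.intervals = [iv for iv in classes[src].intervals if iv.unit_id in teg_ids]
        classes[name] = fcs
    return classes


@dataclass(frozen=True)
class TegAssignment:
    gene_id: str
    is_teg: bool
    te_ids_overlapping: tuple[str, ...]
    superfamilies: frozenset[str]


@dataclass
class TeGeneOverlapCounts:
    """Tallies of TE placement relative to gene structure."""

    n_te_within_cds: int = 0
    n_te_spanning_cds_intron: int = 0


def _overlaps(a: Interval, b: Interval) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def assign_tegs(
    genes: Sequence[GeneModel],
    repeats: Sequence[RepeatFeature],
    scope: str = "genes_star",
    promoter_len: int = 2000,
    genome: Genome | None = None,
) -> list[TegAssignment]:
    """Label each gene as TE-associated (TEG) or not.

    ``scope='gene_body'`` uses the gene span; ``scope='genes_star'`` extends
    it with the promoter. The overlap predicate is >=1 bp on half-open
    intervals.
    """
    if scope not in ("gene_body", "genes_star"):
        raise ValueError(f"unknown TEG scope {scope!r}")
    tes = [
        (r.chrom, (r.start, r.end), r.repeat_id or f"TE_{i + 1}", r.superfamily)
        for i, r in enumerate(repeats)
        if r.repeat_class == "TE"
    ]
    by_chrom: dict[str, list] = {}
    for chrom, iv, rid, fam in tes:
        by_chrom.setdefault(chrom, []).append((iv, rid, fam))
    out = []
    for g in genes:
        span = (g.start, g.end)
        if scope == "genes_star":
            clen = genome.length(g.chrom) if genome is not None else None
            if g.strand == "+":
                s = max(0, g.start - promoter_len)
                e = g.end
            else:
                s = g.start
                e = g.end + promoter_len
                if clen is not None:
                    e = min(clen, e)
            span = (s, e)
        hits = [
            (rid, fam)
            for iv, rid, fam in by_chrom.get(g.chrom, [])
            if _overlaps(span, iv)
        ]
        out.append(
            TegAssignment(
                g.gene_id,
                bool(hits),
                tuple(rid for rid, _ in hits),
                frozenset(fam for _, fam in hits if fam),
            )
        )
    return out


def count_te_gene_overlaps(
    genes: Sequence[GeneModel], repeats: Sequence[RepeatFeature]
) -> TeGeneOverlapCounts:
    """Count TEs fully inside CDS intervals vs TEs overlapping both CDS and
    intron sequence of the same gene."""
    counts = TeGeneOverlapCounts()
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for r in repeats:
        if r.repeat_class != "TE":
            continue
        iv = (r.start, r.end)
        within_cds = spans_both = False
        for g in by_chrom.get(r.chrom, []):
            if not _overlaps(iv, (g.start, g.end)):
                continue
            hits_cds = any(_overlaps(iv, c) for c in g.cds)
            hits_intron = any(_overlaps(iv, c) for c in g.introns)
            contained = any(c[0] <= iv[0] and iv[1] <= c[1] for c in g.cds)
            if contained:
                within_cds = True
            if hits_cds and hits_intron:
                spans_both = True
        if within_cds:
            counts.n_te_within_cds += 1
        if spans_both:
            counts.n_te_spanning_cds_intron += 1
    return counts


def count_adenines(
    genome: Genome, chrom: str, start: int, end: int, strand: str | None
) -> int:
    """Number of adenine positions in [start, end) on the given strand.

    On the forward strand adenines are ``A`` bases; on the reverse strand
    they sit opposite forward-strand ``T`` bases. ``strand=None`` pools both.
    """
    arr = genome.array(chrom)[start:end]
    n_a = int((arr == ord("A")).sum())
    n_t = int((arr == ord("T")).sum())
    if strand == "+":
        return n_a
    if strand == "-":
        return n_t
    return n_a + n_t
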
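"""Readers and writers for the external formats consumed by the pipeline.

All coordinates are normalized to a single internal convention: 0-based,
half-open intervals on the forward strand of the stored sequence. A 6mA site
is stored at the position of the methylated adenine itself, which means the
forward-strand base is ``A`` for a plus-strand site and ``T`` for a
minus-strand site (the adenine lives on the reverse complement).

Supported inputs
----------------
* genome FASTA (via Biopython),
* SMRT-Link-style modified-base GFF3 (feature type ``m6A`` or
  ``modified_base``; attributes ``frac``/``coverage``/``IPDRatio``/``context``
  are accepted and optional),
* a 5-column site TSV: ``chrom<TAB>pos0<TAB>strand<TAB>fraction<TAB>coverage``
  with ``.`` for absent values,
* gene-model GFF3 (via gffutils),
* repeat GFF3/BED-like tables with class labels (TE / SR / LC),
* expression TSV (gene id + one TPM column per replicate) and DEG TSV
  (gene id, log2 fold change, FDR).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_BASES = b"ACGTN"

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


class FormatError(ValueError):
    """A malformed or inconsistent input record."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


class Genome:
    """A set of chromosome sequences with fast byte-array access.

    Sequences are stored as uint8 arrays of ASCII codes so that per-base
    queries (adenine counts, motif context scans) vectorize with numpy.
    """

    def __init__(self, chroms: dict[str, str]):
        if len(set(chroms)) != len(chroms):  # dict guarantees this, kept for API clarity
            raise FormatError("duplicate chromosome ids")
        self._arrays: dict[str, np.ndarray] = {}
        for name, seq in chroms.items():
            arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).copy()
            bad = ~np.isin(arr, np.frombuffer(_BASES, dtype=np.uint8))
            if bad.any():
                raise FormatError(f"non-ACGTN base in chromosome {name!r}")
            self._arrays[name] = arr

    @property
    def chrom_ids(self) -> list[str]:
        return list(self._arrays)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._arrays

    def length(self, chrom: str) -> int:
        return int(self._arrays[chrom].size)

    @property
    def lengths(self) -> dict[str, int]:
        return {c: a.size for c, a in self._arrays.items()}

    def array(self, chrom: str) -> np.ndarray:
        """uint8 ASCII array of the forward strand."""
        return self._arrays[chrom]

    def base(self, chrom: str, pos: int) -> str:
        return chr(self._arrays[chrom][pos])

    def sequence(self, chrom: str, start: int = 0, end: int | None = None) -> str:
        arr = self._arrays[chrom]
        return arr[start : arr.size if end is None else end].tobytes().decode("ascii")

    def total_length(self) -> int:
        return int(sum(a.size for a in self._arrays.values()))


@dataclass(frozen=True, order=True)
class MethylationSite:
    """One called 6mA event.

    ``pos`` is the 0-based forward-strand coordinate of the methylated
    adenine; ``fraction`` and ``coverage`` are ``None`` when the caller did
    not report them.
    """

    chrom: str
    pos: int
    strand: str
    fraction: float | None = None
    coverage: int | None = None

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise FormatError(f"invalid strand {self.strand!r}")


@dataclass(frozen=True)
class RepeatFeature:
    """A repeat annotation interval (0-based half-open)."""

    chrom: str
    start: int
    end: int
    repeat_class: str  # TE, SR or LC
    superfamily: str | None = None
    repeat_id: str | None = None

    def __post_init__(self):
        if not self.start < self.end:
            raise FormatError(f"empty repeat interval {self.chrom}:{self.start}-{self.end}")
        if (self.repeat_class == "TE") != (self.superfamily is not None):
            raise FormatError("superfamily must be present exactly for TE repeats")


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    tpm_replicates: tuple[float, ...]
    tpm_mean: float


@dataclass(frozen=True)
class DegRecord:
    gene_id: str
    log2fc: float
    fdr: float

    @property
    def direction(self) -> str:
        return "up" if self.log2fc > 0 else "down"


@dataclass
class SiteRejectionReport:
    """Counts of records dropped while reading a site file."""

    n_read: int = 0
    n_non_adenine: int = 0
    n_below_min_fraction: int = 0
    n_duplicates: int = 0
    rejected: list[tuple[str, int, str]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# genome FASTA
# ---------------------------------------------------------------------------


def read_genome(path: str | os.PathLike) -> Genome:
    chroms: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in chroms:
            raise FormatError(f"duplicate chromosome id {rec.id!r} in {path}")
        chroms[rec.id] = str(rec.seq)
    if not chroms:
        raise FormatError(f"no sequences in {path}")
    return Genome(chroms)


def write_genome(genome: Genome, path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(genome.sequence(c)), id=c, description="")
        for c in genome.chrom_ids
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# methylation sites
# ---------------------------------------------------------------------------


def _site_base_ok(genome: Genome, chrom: str, pos: int, strand: str) -> bool:
    base = genome.base(chrom, pos)
    return base == ("A" if strand == "+" else "T")


def _parse_opt_float(tok: str) -> float | None:
    return None if tok in (".", "", "NA") else float(tok)


def _parse_opt_int(tok: str) -> int | None:
    return None if tok in (".", "", "NA") else int(round(float(tok)))


def _parse_gff_attributes(field9: str) -> dict[str, str]:
    out = {}
    for item in field9.strip().split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" in item:
            k, v = item.split("=", 1)
        elif " " in item:
            k, v = item.split(" ", 1)
        else:
            k, v = item, ""
        out[k.strip()] = v.strip().strip('"')
    return out


def read_methylation_sites(
    path: str | os.PathLike,
    genome: Genome,
    min_fraction: float = 0.0,
    report: SiteRejectionReport | None = None,
) -> list[MethylationSite]:
    """Read 6mA sites from a modified-base GFF3 or a 5-column TSV.

    The format is sniffed per line: lines with 9 tab-separated fields and a
    feature type of ``m6A``/``modified_base`` are treated as GFF3 (1-based
    closed coordinates), 5-field lines as the plain TSV dialect (0-based).
    Sites whose genome base is not adenine on the recorded strand are
    rejected and counted; sites with a reported fraction below
    ``min_fraction`` are filtered (inclusive boundary: fraction >=
    min_fraction is kept). Duplicates on (chrom, pos, strand) keep the
    maximum fraction.
    """
    if report is None:
        report = SiteRejectionReport()
    best: dict[tuple[str, int, str], MethylationSite] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if len(fields) == 9:
                    ftype = fields[2]
                    if ftype not in ("m6A", "modified_base"):
                        continue
                    chrom, strand = fields[0], fields[6]
                    start1, end1 = int(fields[3]), int(fields[4])
                    if start1 != end1:
                        raise FormatError("modified-base feature wider than 1 bp")
                    pos = start1 - 1  # 1-based closed -> 0-based
                    attrs = _parse_gff_attributes(fields[8])
                    frac = _parse_opt_float(attrs.get("frac", "."))
                    cov = _parse_opt_int(attrs.get("coverage", "."))
                elif len(fields) == 5:
                    chrom, strand = fields[0], fields[2]
                    pos = int(fields[1])
                    frac = _parse_opt_float(fields[3])
                    cov = _parse_opt_int(fields[4])
                else:
                    raise FormatError(f"expected 5 or 9 columns, got {len(fields)}")
                if strand not in ("+", "-"):
                    raise FormatError(f"invalid strand {strand!r}")
            except (ValueError, IndexError) as exc:
                raise FormatError(f"{path}:{lineno}: malformed line: {exc}") from exc

            if chrom not in genome:
                raise FormatError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if not 0 <= pos < genome.length(chrom):
                raise FormatError(f"{path}:{lineno}: position {pos} outside {chrom}")
            report.n_read += 1
            if not _site_base_ok(genome, chrom, pos, strand):
                report.n_non_adenine += 1
                report.rejected.append((chrom, pos, strand))
                continue
            if frac is not None and frac < min_fraction:
                report.n_below_min_fraction += 1
                continue
            key = (chrom, pos, strand)
            prev = best.get(key)
            if prev is not None:
                report.n_duplicates += 1
                if (frac or 0.0) <= (prev.fraction or 0.0):
                    continue
            best[key] = MethylationSite(chrom, pos, strand, frac, cov)
    return sorted(best.values(), key=lambda s: (s.chrom, s.pos, s.strand))


def write_sites_tsv(sites: Iterable[MethylationSite], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for s in sites:
            frac = "." if s.fraction is None else repr(s.fraction)
            cov = "." if s.coverage is None else str(s.coverage)
            fh.write(f"{s.chrom}\t{s.pos}\t{s.strand}\t{frac}\t{cov}\n")


def write_sites_gff(sites: Iterable[MethylationSite], path: str | os.PathLike) -> None:
    """Write sites in the SMRT-Link-style modified-base GFF3 dialect."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for s in sites:
            attrs = []
            if s.coverage is not None:
                attrs.append(f"coverage={s.coverage}")
            if s.fraction is not None:
                attrs.append(f"frac={s.fraction!r}")
            fh.write(
                f"{s.chrom}\tm6amap\tm6A\t{s.pos + 1}\t{s.pos + 1}\t.\t{s.strand}\t.\t"
                + (";".join(attrs) if attrs else ".")
                + "\n"
            )


# ---------------------------------------------------------------------------
# gene models (GFF3, via gffutils)
# ---------------------------------------------------------------------------


def read_gene_models(path: str | os.PathLike):
    """Parse a GFF3 gene annotation into :class:`~m6amap.annotation.GeneModel` objects.

    One mRNA per gene is assumed; if several are present the first by file
    order is used and a warning is logged. Raises on genes without exons or
    with overlapping exons.
    """
    import gffutils

    from .annotation import GeneModel

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        mrnas = list(db.children(gene, featuretype="mRNA", order_by="start"))
        if not mrnas:
            # tolerate gene rows that directly parent exons
            mrna = gene
        else:
            if len(mrnas) > 1:
                logger.warning(
                    "gene %s has %d mRNAs; using the first by file order",
                    gene.id,
                    len(mrnas),
                )
            mrna = mrnas[0]
        exons = sorted(
            (f.start - 1, f.end) for f in db.children(mrna, featuretype="exon")
        )
        if not exons:
            raise FormatError(f"gene {gene.id} has no exons")
        for (s1, e1), (s2, _e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise FormatError(f"gene {gene.id} has overlapping exons")
        cds = sorted((f.start - 1, f.end) for f in db.children(mrna, featuretype="CDS"))
        utr5 = sorted(
            (f.start - 1, f.end)
            for f in db.children(mrna, featuretype="five_prime_UTR")
        )
        utr3 = sorted(
            (f.start - 1, f.end)
            for f in db.children(mrna, featuretype="three_prime_UTR")
        )
        genes.append(
            GeneModel.from_exons(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                exons=exons,
                cds=cds,
                utr5=utr5,
                utr3=utr3,
            )
        )
    return genes


def write_gene_models_gff(genes, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            base = f"{g.chrom}\tm6amap"
            fh.write(
                f"{base}\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            mrna_id = f"{g.gene_id}.t1"
            fh.write(
                f"{base}\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna_id};Parent={g.gene_id}\n"
            )
            for ftype, ivs in (
                ("exon", g.exons),
                ("CDS", g.cds),
                ("five_prime_UTR", g.utr5),
                ("three_prime_UTR", g.utr3),
            ):
                for s, e in ivs:
                    fh.write(
                        f"{base}\t{ftype}\t{s + 1}\t{e}\t.\t{g.strand}\t.\tParent={mrna_id}\n"
                    )


# ---------------------------------------------------------------------------
# repeats
# ---------------------------------------------------------------------------


def read_repeats(path: str | os.PathLike) -> list[RepeatFeature]:
    """Read repeat annotation from GFF3 (class in column 3 or attributes) or a
    BED-like TSV: chrom, start0, end, class, superfamily(.)."""
    repeats: list[RepeatFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if len(fields) == 9:
                    attrs = _parse_gff_attributes(fields[8])
                    rclass = attrs.get("repeat_class", fields[2])
                    superfam = attrs.get("superfamily") or None
                    rid = attrs.get("ID") or None
                    start, end = int(fields[3]) - 1, int(fields[4])
                    chrom = fields[0]
                else:
                    chrom = fields[0]
                    start, end = int(fields[1]), int(fields[2])
                    rclass = fields[3]
                    superfam = (
                        None
                        if len(fields) < 5 or fields[4] in (".", "")
                        else fields[4]
                    )
                    rid = fields[5] if len(fields) > 5 else None
                if rclass not in ("TE", "SR", "LC"):
                    raise FormatError(f"unknown repeat class {rclass!r}")
                repeats.append(
                    RepeatFeature(chrom, start, end, rclass, superfam, rid)
                )
            except (ValueError, IndexError) as exc:
                raise FormatError(f"{path}:{lineno}: malformed repeat line: {exc}") from exc
    return repeats


def write_repeats_gff(repeats: Sequence[RepeatFeature], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, r in enumerate(repeats):
            attrs = [f"ID={r.repeat_id or f'rep_{i + 1}'}", f"repeat_class={r.repeat_class}"]
            if r.superfamily:
                attrs.append(f"superfamily={r.superfamily}")
            fh.write(
                f"{r.chrom}\tm6amap\t{r.repeat_class}\t{r.start + 1}\t{r.end}\t.\t.\t.\t"
                + ";".join(attrs)
                + "\n"
            )


# ---------------------------------------------------------------------------
# expression / DEG tables
# ---------------------------------------------------------------------------


def read_expression(path: str | os.PathLike) -> list[ExpressionRecord]:
    """Expression TSV: header row, gene_id then one column per replicate."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected gene_id plus >=1 TPM column")
    recs = []
    for row in df.itertuples(index=False):
        tpms = tuple(float(v) for v in row[1:])
        if any(t < 0 for t in tpms):
            raise FormatError(f"negative TPM for gene {row[0]}")
        recs.append(ExpressionRecord(str(row[0]), tpms, float(np.mean(tpms))))
    return recs


def write_expression(records: Sequence[ExpressionRecord], path: str | os.PathLike) -> None:
    n_rep = max(len(r.tpm_replicates) for r in records) if records else 1
    with open(path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(f"tpm_rep{i + 1}" for i in range(n_rep)) + "\n")
        for r in records:
            fh.write(r.gene_id + "\t" + "\t".join(f"{t:g}" for t in r.tpm_replicates) + "\n")


def read_degs(path: str | os.PathLike) -> list[DegRecord]:
    df = pd.read_csv(path, sep="\t")
    need = {"gene_id", "log2fc", "fdr"}
    if not need.issubset(df.columns):
        raise FormatError(f"{path}: DEG table must have columns {sorted(need)}")
    return [
        DegRecord(str(r.gene_id), float(r.log2fc), float(r.fdr))
        for r in df.itertuples(index=False)
    ]


def write_degs(degs: Sequence[DegRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tlog2fc\tfdr\n")
        for d in degs:
            fh.write(f"{d.gene_id}\t{d.log2fc:g}\t{d.fdr:g}\n")


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


def write_hotspots_bed(hotspots, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for i, h in enumerate(hotspots):
            fh.write(f"{h.chrom}\t{h.start}\t{h.end}\thotspot_{i + 1}\t{h.n_sites}\n")


def write_results(
    tables: dict[str, pd.DataFrame],
    outdir: str | os.PathLike,
    manifest: dict | None = None,
) -> dict[str, str]:
    """Write one TSV per named table plus an optional JSON run manifest."""
    os.makedirs(outdir, exist_ok=True)
    written = {}
    for name, df in tables.items():
        path = os.path.join(str(outdir), f"{name}.tsv")
        df.to_csv(path, sep="\t", index=False)
        written[name] = path
    if manifest is not None:
        path = os.path.join(str(outdir), "manifest.json")
        with open(path, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        written["manifest"] = path
    return written


def sites_by_chrom(
    sites: Sequence[MethylationSite],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Group sites into per-chromosome (positions, strand=='+') numpy arrays,
    sorted by position."""
    out: dict[str, tuple[list[int], list[bool]]] = {}
    for s in sites:
        pos, plus = out.setdefault(s.chrom, ([], []))
        pos.append(s.pos)
        plus.append(s.strand == "+")
    result = {}
    for chrom, (pos, plus) in out.items():
        p = np.asarray(pos, dtype=np.int64)
        b = np.asarray(plus, dtype=bool)
        order = np.argsort(p, kind="stable")
        result[chrom] = (p[order], b[order])
    return result
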
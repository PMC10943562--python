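"""Synthetic genome / methylome / expression generator with planted truth.

Generates a chromosome-scale genome (i.i.d. uniform bases), non-overlapping
intron-rich gene models with UTRs and promoter clearance, repeat annotation
(TE superfamilies plus simple repeats and low-complexity runs), a 6mA
methylome with known planted structure, replicate expression tables coupled
to gene-body methylation, and mutant methylomes, so that every analysis
stage of the package has a recoverable ground truth at desk scale.

Methylome model
---------------
Each adenine position (either strand) receives a relative hazard

    w = motif_factor^[AGGYV context]  x  body_ramp(t)  x  tts_bump(d)
        x  donor_bump^[offset -2/-1 of a splice donor]  x  te_factor^[in TE]

and sites are drawn as independent Bernoulli events with probability
proportional to w. ``base_rate`` is the *target global 6mA/A density*: the
hazard is normalized so the expected number of sites, including the sites
planted in hotspots, equals ``base_rate`` times the number of adenines
(per-site probabilities are capped at 1). Hotspots are planted afterwards as
runs of ``hotspot_sites`` sites with spacing below 100 bp at random
intergenic loci, so their ground-truth intervals are exact. Per-site
methylated fractions are drawn Uniform(0.1, 0.8).

Mutant models: ``demethylase_ko`` keeps all WT sites and adds extra sites at
(factor - 1) times the calibrated hazard (a lost eraser accumulates marks on
top of the WT pattern); ``methylase_ko`` removes each gene's body sites with
the configured probability and adds fresh churn sites. Replicates are
independent Bernoulli thinnings at the configured coverage retention.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np

from .annotation import GeneModel, build_feature_sets, _merge_intervals, _complement
from .io_formats import (
    DegRecord,
    ExpressionRecord,
    Genome,
    MethylationSite,
    RepeatFeature,
    write_degs,
    write_expression,
    write_gene_models_gff,
    write_genome,
    write_repeats_gff,
    write_sites_gff,
    write_sites_tsv,
)
from .diffmeth import SampleMethylome

logger = logging.getLogger(__name__)

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Study-condition parameters of the synthetic dataset.

    The default scale is 20 chromosomes x 100 kb with 600 intron-rich genes
    (a chromosome-scale ~31-Mb, ~10k-gene genome at roughly 1/15 scale).
    Effect sizes default to the observed landscape they emulate: ~0.1%
    global 6mA/A, AGGYV-context preference, a 5'->3' gene-body ramp, a TTS
    peak, a x6 splice-donor bump at transcription offsets -2/-1, TE
    enrichment, planted dense hotspots, and expression positively coupled
    to gene-body 6mA.
    """

    seed: int = 0
    n_chrom: int = 20
    chrom_len: int = 100_000
    n_genes: int = 600
    exons_per_gene: tuple[int, int] = (7, 9)  # inclusive uniform range
    exon_len: tuple[int, int] = (80, 130)
    intron_len: tuple[int, int] = (50, 100)
    utr5_len: int = 50
    utr3_len: int = 80
    promoter_len: int = 2000
    te_fraction: float = 0.08
    te_len: tuple[int, int] = (500, 3000)
    te_superfamily_mix: dict[str, float] = field(
        default_factory=lambda: {
            "DNA/CMC-EnSpm": 0.6,
            "LTR/Gypsy": 0.2,
            "LINE/L1": 0.1,
            "DNA/hAT": 0.1,
        }
    )
    sr_fraction: float = 0.005
    lc_fraction: float = 0.005
    simple_repeat_len: tuple[int, int] = (50, 200)
    base_rate: float = 0.001
    motif_factor: float = 10.0
    body_gradient: tuple[float, float] = (0.5, 1.5)
    tts_peak: tuple[float, float] = (5.0, 150.0)  # (height multiplier, Gaussian sd bp)
    donor_bump: float = 6.0
    te_factor: float = 5.0
    n_hotspots: int = 5
    hotspot_sites: int = 20
    hotspot_spacing: tuple[int, int] = (40, 80)
    fraction_range: tuple[float, float] = (0.1, 0.8)
    mean_coverage: float = 100.0
    expr_intercept: float = 3.0
    expr_slope: float = 0.5
    expr_noise_sd: float = 2.0
    n_expr_replicates: int = 3
    n_replicates: int = 2
    replicate_retention: float = 0.95
    mutant_model: dict[str, float] = field(
        default_factory=lambda: {"demethylase_ko": 1.213}
    )

    def validate(self) -> None:
        for frac in (self.te_fraction, self.sr_fraction, self.lc_fraction,
                     self.replicate_retention):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must be in [0, 1]")
        for mult in (self.motif_factor, self.donor_bump, self.te_factor,
                     *self.body_gradient, self.tts_peak[0]):
            if mult <= 0:
                raise ValueError("multipliers must be positive")
        if not 0 < self.base_rate < 1:
            raise ValueError("base_rate must be in (0, 1)")
        if self.hotspot_sites < 10:
            raise ValueError("hotspot_sites must be >= 10")
        if self.hotspot_spacing[1] >= 100:
            raise ValueError("hotspot spacing must stay below 100 bp")


@dataclass
class SyntheticTruth:
    """Planted ground truth, sufficient to verify every recovery property."""

    hotspot_intervals: list[tuple[str, int, int]]
    per_gene_body_count: dict[str, int]
    expr_intercept: float
    expr_slope: float
    hazard_scale: float
    n_baseline_sites: int
    n_planted_sites: int
    mutant_model: dict[str, float]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# genome + annotation
# ---------------------------------------------------------------------------


def simulate_genome_annotation(
    config: SimulationConfig,
) -> tuple[Genome, list[GeneModel], list[RepeatFeature]]:
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    chroms = {}
    for i in range(config.n_chrom):
        seq = _BASE_BYTES[rng.integers(0, 4, config.chrom_len)].tobytes().decode("ascii")
        chroms[f"chr{i + 1}"] = seq
    genome = Genome(chroms)

    # Genes are packed greedily across chromosomes. The 2-kb promoter
    # clearance is strand-aware: it is only needed on the promoter side of
    # each gene, so a (+ gene, - gene) head-to-head pair needs no clearance
    # between the first gene's end and the second gene's start.
    genes: list[GeneModel] = []
    chrom_iter = iter(genome.chrom_ids)
    chrom = next(chrom_iter)
    cursor = config.promoter_len + int(rng.integers(50, 300))
    prev_strand = "+"
    limit = config.chrom_len - 500
    while len(genes) < config.n_genes:
        n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        ex_lens = rng.integers(config.exon_len[0], config.exon_len[1] + 1, n_ex)
        in_lens = rng.integers(config.intron_len[0], config.intron_len[1] + 1, n_ex - 1)
        span = int(ex_lens.sum() + in_lens.sum())
        strand = "+" if rng.random() < 0.5 else "-"
        clearance = (
            config.promoter_len
            if (strand == "+" or prev_strand == "-")
            else 0
        )
        start = cursor + clearance + int(rng.integers(100, 300))
        if start + span + (config.promoter_len if strand == "-" else 0) > limit:
            try:
                chrom = next(chrom_iter)
            except StopIteration:
                raise ValueError(
                    f"infeasible packing: {config.n_genes} genes of this size "
                    f"do not fit on {config.n_chrom} x {config.chrom_len} bp"
                ) from None
            cursor = config.promoter_len + int(rng.integers(50, 300))
            prev_strand = "+"
            continue
        exons = []
        p = start
        for k in range(n_ex):
            exons.append((p, p + int(ex_lens[k])))
            p += int(ex_lens[k])
            if k < n_ex - 1:
                p += int(in_lens[k])
        gid = f"g{len(genes) + 1:04d}"
        genes.append(_with_utrs(gid, chrom, strand, exons, config))
        cursor = p
        prev_strand = strand

    repeats = _simulate_repeats(genome, genes, config, rng)
    return genome, genes, repeats


def _with_utrs(gid, chrom, strand, exons, config) -> GeneModel:
    """Carve 5'/3' UTRs out of the terminal exons; the rest is CDS."""
    first, last = exons[0], exons[-1]
    if strand == "+":
        utr5 = [(first[0], first[0] + config.utr5_len)]
        utr3 = [(last[1] - config.utr3_len, last[1])]
    else:
        utr5 = [(last[1] - config.utr5_len, last[1])]
        utr3 = [(first[0], first[0] + config.utr3_len)]
    cds = []
    for s, e in exons:
        cs, ce = s, e
        for us, ue in utr5 + utr3:
            if us <= cs < ue:
                cs = ue
            if us < ce <= ue:
                ce = us
        if cs < ce:
            cds.append((cs, ce))
    return GeneModel.from_exons(
        gene_id=gid, chrom=chrom, strand=strand, exons=exons,
        cds=cds, utr5=utr5, utr3=utr3,
    )


def _simulate_repeats(genome, genes, config, rng) -> list[RepeatFeature]:
    repeats: list[RepeatFeature] = []
    fams = list(config.te_superfamily_mix)
    probs = np.array([config.te_superfamily_mix[f] for f in fams])
    probs = probs / probs.sum()
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.chrom_ids}
    total = genome.total_length()
    chrom_ids = genome.chrom_ids

    def place(target_bp, length_range, make):
        placed = 0
        attempts = 0
        while placed < target_bp and attempts < 100_000:
            attempts += 1
            chrom = chrom_ids[int(rng.integers(0, len(chrom_ids)))]
            length = int(rng.integers(length_range[0], length_range[1] + 1))
            clen = genome.length(chrom)
            if length >= clen:
                continue
            start = int(rng.integers(0, clen - length))
            iv = (start, start + length)
            if any(s < iv[1] and iv[0] < e for s, e in occupied[chrom]):
                continue
            occupied[chrom].append(iv)
            repeats.append(make(chrom, iv))
            placed += length

    n_te = [0]

    def make_te(chrom, iv):
        n_te[0] += 1
        fam = fams[int(rng.choice(len(fams), p=probs))]
        return RepeatFeature(chrom, iv[0], iv[1], "TE", fam, f"TE_{n_te[0]}")

    n_simple = [0]

    def make_simple(rclass):
        def make(chrom, iv):
            n_simple[0] += 1
            return RepeatFeature(chrom, iv[0], iv[1], rclass, None, f"{rclass}_{n_simple[0]}")
        return make

    place(int(config.te_fraction * total), config.te_len, make_te)
    place(int(config.sr_fraction * total), config.simple_repeat_len, make_simple("SR"))
    place(int(config.lc_fraction * total), config.simple_repeat_len, make_simple("LC"))
    return repeats


# ---------------------------------------------------------------------------
# methylome
# ---------------------------------------------------------------------------


def _iupac_byte_mask(letters: str) -> np.ndarray:
    mask = np.zeros(256, dtype=bool)
    for b in letters:
        mask[ord(b)] = True
    return mask


_IS = {c: _iupac_byte_mask(s) for c, s in
       (("A", "A"), ("C", "C"), ("G", "G"), ("T", "T"),
        ("Y", "CT"), ("V", "ACG"), ("R", "AG"), ("B", "CGT"))}


def _aggyv_masks(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks over forward positions whose plus-strand (resp.
    minus-strand) adenine sits in an AGGYV context read 5'->3' on that
    strand."""
    n = arr.size

    def shifted(mask_lookup, off):
        out = np.zeros(n, dtype=bool)
        if off >= 0:
            out[: n - off] = mask_lookup[arr[off:]]
        else:
            out[-off:] = mask_lookup[arr[: n + off]]
        return out

    plus = (
        _IS["A"][arr]
        & shifted(_IS["G"], 1)
        & shifted(_IS["G"], 2)
        & shifted(_IS["Y"], 3)
        & shifted(_IS["V"], 4)
    )
    # minus strand: A at forward pos i is forward-strand T; motif bases at
    # minus offsets +k are complements of forward positions i-k
    minus = (
        _IS["T"][arr]
        & shifted(_IS["C"], -1)
        & shifted(_IS["C"], -2)
        & shifted(_IS["R"], -3)  # complement of Y
        & shifted(_IS["B"], -4)  # complement of V
    )
    return plus, minus


def _hazard_weights(genome, genes, repeats, config):
    """Per-chromosome (w_plus, w_minus) relative hazard arrays over all
    forward positions (nonzero only where the strand base is adenine)."""
    weights = {}
    te_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in repeats:
        if r.repeat_class == "TE":
            te_by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)
    g0, g1 = config.body_gradient
    height, sd = config.tts_peak
    for chrom in genome.chrom_ids:
        arr = genome.array(chrom)
        n = arr.size
        mult = np.ones(n)  # strand-shared positional multipliers
        w_plus = np.where(arr == ord("A"), 1.0, 0.0)
        w_minus = np.where(arr == ord("T"), 1.0, 0.0)
        aggyv_p, aggyv_m = _aggyv_masks(arr)
        w_plus[aggyv_p] *= config.motif_factor
        w_minus[aggyv_m] *= config.motif_factor
        for s, e in te_by_chrom.get(chrom, []):
            mult[s:e] *= config.te_factor
        strand_mult = {"+": np.ones(n), "-": np.ones(n)}
        for g in genes_by_chrom.get(chrom, []):
            sm = strand_mult[g.strand]
            t = np.arange(g.length) / g.length
            if g.strand == "-":
                t = t[::-1]
            sm[g.start : g.end] *= g0 + (g1 - g0) * t
            # TTS Gaussian bump
            lo = max(0, g.tts - int(4 * sd))
            hi = min(n, g.tts + int(4 * sd) + 1)
            d = np.arange(lo, hi) - g.tts
            sm[lo:hi] *= 1 + (height - 1) * np.exp(-(d**2) / (2 * sd**2))
            # donor bump at transcription offsets -2, -1
            for s, e in g.introns:
                if g.strand == "+":
                    j0, j1 = max(0, s - 2), s
                else:
                    j0, j1 = e, min(n, e + 2)
                sm[j0:j1] *= config.donor_bump
        w_plus *= mult * strand_mult["+"]
        w_minus *= mult * strand_mult["-"]
        weights[chrom] = (w_plus, w_minus)
    return weights


def _plant_hotspots(genome, genes, config, rng):
    """Pick intergenic loci and lay down dense site runs; returns
    (sites, intervals)."""
    star_by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.chrom_ids}
    for g in genes:
        if g.strand == "+":
            s = max(0, g.start - config.promoter_len)
            star_by_chrom[g.chrom].append((s, g.end))
        else:
            star_by_chrom[g.chrom].append(
                (g.start, min(genome.length(g.chrom), g.end + config.promoter_len))
            )
    # roomy intergenic intervals
    max_span = config.hotspot_sites * (config.hotspot_spacing[1] + 20)
    candidates = []
    for chrom in genome.chrom_ids:
        for s, e in _complement(_merge_intervals(star_by_chrom[chrom]), genome.length(chrom)):
            if e - s >= max_span:
                candidates.append((chrom, s, e))
    if len(candidates) == 0 and config.n_hotspots > 0:
        raise ValueError("no intergenic interval large enough to plant a hotspot")
    sites: list[MethylationSite] = []
    intervals = []
    lo_sp, hi_sp = config.hotspot_spacing
    weights = np.array([e - s for _, s, e in candidates], dtype=float)
    weights /= weights.sum()
    # keep planted hotspots well separated so they never chain into one run
    margin = 300
    taken: list[tuple[str, int, int]] = []
    for _ in range(config.n_hotspots):
        start = None
        for _attempt in range(1000):
            chrom, s, e = candidates[int(rng.choice(len(candidates), p=weights))]
            cand = int(rng.integers(s, e - max_span + 1))
            iv = (cand - margin, cand + max_span + margin)
            if all(c != chrom or not (ts < iv[1] and iv[0] < te) for c, ts, te in taken):
                start = cand
                taken.append((chrom, iv[0], iv[1]))
                break
        if start is None:
            raise ValueError("could not place non-overlapping hotspots")
        arr = genome.array(chrom)
        positions = []
        strands = []
        pos = start
        while len(positions) < config.hotspot_sites:
            step = int(rng.integers(lo_sp, hi_sp + 1)) if positions else 0
            pos = pos + step
            while pos < arr.size and arr[pos] not in (ord("A"), ord("T")):
                pos += 1
            if pos >= arr.size:
                break
            positions.append(pos)
            strands.append("+" if arr[pos] == ord("A") else "-")
            pos += 1
        if len(positions) < config.hotspot_sites:
            continue
        # pos was advanced by 1 after the last accepted site
        positions = positions[: config.hotspot_sites]
        frac = rng.uniform(*config.fraction_range, len(positions))
        cov = rng.poisson(config.mean_coverage, len(positions)).clip(min=10)
        for p, st, f, c in zip(positions, strands, frac, cov):
            sites.append(MethylationSite(chrom, int(p), st, float(f), int(c)))
        intervals.append((chrom, int(positions[0]), int(positions[-1]) + 1))
    return sites, intervals


def simulate_methylome(
    genome: Genome,
    genes: list[GeneModel],
    repeats: list[RepeatFeature],
    config: SimulationConfig,
) -> tuple[list[MethylationSite], SyntheticTruth]:
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    planted, hotspot_ivs = _plant_hotspots(genome, genes, config, rng)
    weights = _hazard_weights(genome, genes, repeats, config)

    total_a = sum(
        float((w[0] > 0).sum() + (w[1] > 0).sum()) for w in weights.values()
    )
    total_w = sum(float(w[0].sum() + w[1].sum()) for w in weights.values())
    target = config.base_rate * total_a
    budget = max(target - len(planted), 0.0)
    scale = budget / total_w if total_w > 0 else 0.0

    sites: dict[tuple[str, int, str], MethylationSite] = {
        (s.chrom, s.pos, s.strand): s for s in planted
    }
    n_capped = 0
    n_baseline = 0
    for chrom in genome.chrom_ids:
        w_plus, w_minus = weights[chrom]
        for strand, w in (("+", w_plus), ("-", w_minus)):
            p = w * scale
            n_capped += int((p > 1).sum())
            np.clip(p, None, 1.0, out=p)
            draws = np.nonzero(rng.random(p.size) < p)[0]
            frac = rng.uniform(*config.fraction_range, draws.size)
            cov = rng.poisson(config.mean_coverage, draws.size).clip(min=10)
            for pos, f, c in zip(draws, frac, cov):
                key = (chrom, int(pos), strand)
                if key not in sites:
                    sites[key] = MethylationSite(chrom, int(pos), strand, float(f), int(c))
                    n_baseline += 1
    if n_capped > 0.01 * total_a:
        logger.warning(
            "deposition probability capped at 1 for %d adenines; effect sizes "
            "may be too large",
            n_capped,
        )
    site_list = sorted(sites.values(), key=lambda s: (s.chrom, s.pos, s.strand))
    per_gene = _per_gene_body_counts(genes, site_list)
    truth = SyntheticTruth(
        hotspot_intervals=hotspot_ivs,
        per_gene_body_count=per_gene,
        expr_intercept=config.expr_intercept,
        expr_slope=config.expr_slope,
        hazard_scale=scale,
        n_baseline_sites=n_baseline,
        n_planted_sites=len(planted),
        mutant_model=dict(config.mutant_model),
    )
    return site_list, truth


def _per_gene_body_counts(genes, sites) -> dict[str, int]:
    from .io_formats import sites_by_chrom

    grouped = sites_by_chrom(sites)
    out = {}
    for g in genes:
        if g.chrom in grouped:
            pos, plus = grouped[g.chrom]
            lo, hi = np.searchsorted(pos, [g.start, g.end])
            sel = plus[lo:hi] if g.strand == "+" else ~plus[lo:hi]
            out[g.gene_id] = int(sel.sum())
        else:
            out[g.gene_id] = 0
    return out


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def simulate_expression(
    genes: list[GeneModel],
    body_counts: dict[str, int],
    config: SimulationConfig,
    seed_tag: int = 3,
) -> list[ExpressionRecord]:
    """log2(TPM + 1) = intercept + slope * body_site_count + N(0, noise_sd),
    truncated at 0; replicates drawn i.i.d."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, seed_tag]))
    records = []
    for g in genes:
        mu = config.expr_intercept + config.expr_slope * body_counts.get(g.gene_id, 0)
        log2_tpm1 = np.maximum(
            mu + rng.normal(0, config.expr_noise_sd, config.n_expr_replicates), 0.0
        )
        tpm = np.maximum(np.exp2(log2_tpm1) - 1, 0.0)
        records.append(
            ExpressionRecord(g.gene_id, tuple(float(t) for t in tpm), float(tpm.mean()))
        )
    return records


def simulate_mutant_degs(
    genes: list[GeneModel],
    wt_counts: dict[str, int],
    mut_counts: dict[str, int],
    config: SimulationConfig,
) -> list[DegRecord]:
    """DEGs implied by the true expression model: genes whose model-mean TPM
    changes more than twofold between genotypes (the upstream DE contract:
    FDR <= 0.001, |fold change| > 2)."""
    degs = []
    for g in genes:
        delta = config.expr_slope * (
            mut_counts.get(g.gene_id, 0) - wt_counts.get(g.gene_id, 0)
        )
        if abs(delta) > 1.0:  # >2-fold on the TPM scale
            degs.append(DegRecord(g.gene_id, float(delta), 1e-4))
    return degs


# ---------------------------------------------------------------------------
# mutants and replicates
# ---------------------------------------------------------------------------


def _thin(sites, retention, rng) -> list[MethylationSite]:
    keep = rng.random(len(sites)) < retention
    return [s for s, k in zip(sites, keep) if k]


def simulate_mutant(
    wt_sites: list[MethylationSite],
    genome: Genome,
    genes: list[GeneModel],
    repeats: list[RepeatFeature],
    config: SimulationConfig,
) -> tuple[list[SampleMethylome], list[SampleMethylome], list[MethylationSite]]:
    """Build per-replicate WT and mutant methylomes.

    Returns (wt_replicates, mutant_replicates, mutant_base_sites).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    model = dict(config.mutant_model)
    mut_sites: dict[tuple[str, int, str], MethylationSite] = {
        (s.chrom, s.pos, s.strand): s for s in wt_sites
    }
    if "demethylase_ko" in model:
        factor = model["demethylase_ko"]
        if factor < 1:
            raise ValueError("demethylase_ko factor must be >= 1")
        weights = _hazard_weights(genome, genes, repeats, config)
        total_a = sum(
            float((w[0] > 0).sum() + (w[1] > 0).sum()) for w in weights.values()
        )
        total_w = sum(float(w[0].sum() + w[1].sum()) for w in weights.values())
        scale = config.base_rate * total_a / total_w if total_w else 0.0
        extra_scale = scale * (factor - 1)
        for chrom in genome.chrom_ids:
            w_plus, w_minus = weights[chrom]
            for strand, w in (("+", w_plus), ("-", w_minus)):
                p = np.clip(w * extra_scale, None, 1.0)
                draws = np.nonzero(rng.random(p.size) < p)[0]
                frac = rng.uniform(*config.fraction_range, draws.size)
                cov = rng.poisson(config.mean_coverage, draws.size).clip(min=10)
                for pos, f, c in zip(draws, frac, cov):
                    key = (chrom, int(pos), strand)
                    if key not in mut_sites:
                        mut_sites[key] = MethylationSite(
                            chrom, int(pos), strand, float(f), int(c)
                        )
    if "methylase_ko" in model:
        # each gene either loses its body sites entirely (prob = removal) or
        # has them redrawn from the calibrated hazard, producing the
        # marked/unmarked churn of a disturbed writer
        removal = model["methylase_ko"]
        if not 0 <= removal <= 1:
            raise ValueError("methylase_ko removal probability must be in [0, 1]")
        weights = _hazard_weights(genome, genes, repeats, config)
        total_a = sum(
            float((w[0] > 0).sum() + (w[1] > 0).sum()) for w in weights.values()
        )
        total_w = sum(float(w[0].sum() + w[1].sum()) for w in weights.values())
        scale = config.base_rate * total_a / total_w if total_w else 0.0
        for g in genes:
            removed = rng.random() < removal
            for key in [k for k in mut_sites
                        if k[0] == g.chrom and g.start <= k[1] < g.end]:
                del mut_sites[key]
            if removed:
                continue
            w_plus, w_minus = weights[g.chrom]
            for strand, w in (("+", w_plus), ("-", w_minus)):
                seg = np.clip(w[g.start : g.end] * scale, None, 1.0)
                draws = np.nonzero(rng.random(seg.size) < seg)[0] + g.start
                frac = rng.uniform(*config.fraction_range, draws.size)
                for pos, f in zip(draws, frac):
                    key = (g.chrom, int(pos), strand)
                    if key not in mut_sites:
                        mut_sites[key] = MethylationSite(
                            g.chrom, int(pos), strand, float(f), None
                        )
    mutant_base = sorted(mut_sites.values(), key=lambda s: (s.chrom, s.pos, s.strand))
    wt_reps = [
        SampleMethylome(
            sample_id=f"WT_{i + 1}",
            genotype="WT",
            replicate=str(i + 1),
            sites=_thin(wt_sites, config.replicate_retention, rng),
            _genome=genome,
        )
        for i in range(config.n_replicates)
    ]
    mut_reps = [
        SampleMethylome(
            sample_id=f"MUT_{i + 1}",
            genotype="mutant",
            replicate=str(i + 1),
            sites=_thin(mutant_base, config.replicate_retention, rng),
            _genome=genome,
        )
        for i in range(config.n_replicates)
    ]
    return wt_reps, mut_reps, mutant_base


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    genome: Genome
    genes: list[GeneModel]
    repeats: list[RepeatFeature]
    sites: list[MethylationSite]
    truth: SyntheticTruth
    expression: list[ExpressionRecord]
    wt_replicates: list[SampleMethylome]
    mut_replicates: list[SampleMethylome]
    mutant_sites: list[MethylationSite]
    degs: list[DegRecord]


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Run every generator stage with seeds derived from ``config.seed``."""
    genome, genes, repeats = simulate_genome_annotation(config)
    sites, truth = simulate_methylome(genome, genes, repeats, config)
    expression = simulate_expression(genes, truth.per_gene_body_count, config)
    wt_reps, mut_reps, mutant_sites = simulate_mutant(
        sites, genome, genes, repeats, config
    )
    mut_counts = _per_gene_body_counts(genes, mutant_sites)
    degs = simulate_mutant_degs(genes, truth.per_gene_body_count, mut_counts, config)
    return SyntheticDataset(
        config=config,
        genome=genome,
        genes=genes,
        repeats=repeats,
        sites=sites,
        truth=truth,
        expression=expression,
        wt_replicates=wt_reps,
        mut_replicates=mut_reps,
        mutant_sites=mutant_sites,
        degs=degs,
    )


def write_dataset(ds: SyntheticDataset, outdir: str | os.PathLike) -> dict[str, str]:
    os.makedirs(outdir, exist_ok=True)
    outdir = str(outdir)
    paths = {
        "genome": os.path.join(outdir, "genome.fasta"),
        "genes": os.path.join(outdir, "genes.gff3"),
        "repeats": os.path.join(outdir, "repeats.gff3"),
        "sites_tsv": os.path.join(outdir, "sites.tsv"),
        "sites_gff": os.path.join(outdir, "sites.gff3"),
        "expression": os.path.join(outdir, "expression.tsv"),
        "degs": os.path.join(outdir, "degs.tsv"),
        "truth": os.path.join(outdir, "truth.json"),
        "mutant_sites_tsv": os.path.join(outdir, "mutant_sites.tsv"),
    }
    write_genome(ds.genome, paths["genome"])
    write_gene_models_gff(ds.genes, paths["genes"])
    write_repeats_gff(ds.repeats, paths["repeats"])
    write_sites_tsv(ds.sites, paths["sites_tsv"])
    write_sites_gff(ds.sites, paths["sites_gff"])
    write_expression(ds.expression, paths["expression"])
    write_degs(ds.degs, paths["degs"])
    write_sites_tsv(ds.mutant_sites, paths["mutant_sites_tsv"])
    for rep in ds.wt_replicates + ds.mut_replicates:
        p = os.path.join(outdir, f"sites_{rep.sample_id}.tsv")
        write_sites_tsv(rep.sites, p)
        paths[f"sites_{rep.sample_id}"] = p
    with open(paths["truth"], "w") as fh:
        fh.write(ds.truth.to_json())
    return paths
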
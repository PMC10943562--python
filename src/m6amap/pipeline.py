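"""Stage orchestration: run the analysis stages in dependency order and
produce per-stage TSV tables, a JSON summary report and a run manifest.

Stages: simulate (optional), landscape, metagene, associate, diffmeth
(when replicate methylomes are available), enrich (when a COG map is given),
report. Configuration is a flat key/value mapping (YAML on disk); CLI flags
override config keys. One master seed; per-stage seeds are derived by fixed
offsets so each stage is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .annotation import assign_tegs, build_feature_sets, count_te_gene_overlaps
from .diffmeth import SampleMethylome, gene_level_diff, global_shift, overlay_deg
from .expression import (
    class_expression_table,
    occupancy_by_expression,
    summarize_gene_methylation,
    tpm_bin_fractions,
)
from .io_formats import (
    read_degs,
    read_expression,
    read_gene_models,
    read_genome,
    read_methylation_sites,
    read_repeats,
    write_hotspots_bed,
    write_results,
)
from .landscape import (
    annotate_hotspot_te_overlap,
    call_hotspots,
    context_stats,
    feature_methylation_stats,
    hotspot_te_permutation,
    intersite_intervals,
)
from .metagene import (
    donor_offset_profile,
    gene_body_profile,
    intron_profile,
    window_profile,
)

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "landscape", "metagene", "associate", "diffmeth", "enrich")

DEFAULTS = {
    "seed": 0,
    "min_fraction": 0.0,
    "min_sites": 10,
    "gap_max": 100,
    "n_perm": 1000,
    "promoter_len": 2000,
    "grid": 1000,
    "intron_grid": 200,
    "window": 1000,
    "donor_w": 10,
    "lowess_f": 0.05,
    "tss_window_up": 300,
    "tss_window_down": 100,
    "tts_window": 500,
    "high_tpm": 100.0,
    "active_tpm": 1.0,
    "fc_up": 2.0,
    "fc_down": 0.5,
    "strand_policy": "gene_strand",
}


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _profile_table(profile, label: str) -> pd.DataFrame:
    return pd.DataFrame(
        {"grid_index": np.arange(profile.grid_length), label: profile.values}
    )


def run_pipeline(
    config: dict[str, Any],
    outdir: str | os.PathLike,
    stages: tuple[str, ...] = ALL_STAGES,
) -> dict[str, Any]:
    """Execute the requested stages; returns the summary report dict.

    ``config`` holds input paths (``genome``, ``genes``, ``repeats``,
    ``sites``, ``expression``, ``degs``, ``wt_sites``/``mut_sites`` lists,
    ``cog_map``) and parameters (see ``DEFAULTS``). With the ``simulate``
    stage the inputs are generated into ``outdir/simulated`` first.
    """
    params = dict(DEFAULTS)
    params.update({k: v for k, v in config.items() if v is not None})
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    defaults_used = sorted(set(DEFAULTS) - set(k for k, v in config.items() if v is not None))
    logger.info("defaults in effect: %s", defaults_used)

    report: dict[str, Any] = {"version": __version__, "seed": params["seed"]}
    tables: dict[str, pd.DataFrame] = {}

    if "simulate" in stages:
        from .simulate import SimulationConfig, simulate_dataset, write_dataset

        sim_keys = {f.name for f in dataclasses.fields(SimulationConfig)}
        sim_cfg = SimulationConfig(
            **{k: v for k, v in params.items() if k in sim_keys}
        )
        ds = simulate_dataset(sim_cfg)
        sim_paths = write_dataset(ds, os.path.join(outdir, "simulated"))
        params.setdefault("genome", sim_paths["genome"])
        for key, path_key in (
            ("genome", "genome"),
            ("genes", "genes"),
            ("repeats", "repeats"),
            ("sites", "sites_tsv"),
            ("expression", "expression"),
            ("degs", "degs"),
        ):
            if not config.get(key):
                params[key] = sim_paths[path_key]
        params["wt_sites"] = [
            sim_paths[f"sites_{r.sample_id}"] for r in ds.wt_replicates
        ]
        params["mut_sites"] = [
            sim_paths[f"sites_{r.sample_id}"] for r in ds.mut_replicates
        ]
        report["simulate"] = {
            "n_sites": len(ds.sites),
            "n_genes": len(ds.genes),
            "n_hotspots_planted": len(ds.truth.hotspot_intervals),
        }

    for key in ("genome", "genes", "sites"):
        if not params.get(key):
            raise ValueError(f"stage inputs missing: {key!r} (did an upstream stage run?)")
    genome = read_genome(params["genome"])
    genes = read_gene_models(params["genes"])
    repeats = read_repeats(params["repeats"]) if params.get("repeats") else []
    sites = read_methylation_sites(
        params["sites"], genome, min_fraction=params["min_fraction"]
    )
    expression = (
        read_expression(params["expression"]) if params.get("expression") else None
    )
    degs = read_degs(params["degs"]) if params.get("degs") else None
    classes = build_feature_sets(
        genes, repeats, genome, promoter_len=params["promoter_len"]
    )
    teg = assign_tegs(
        genes, repeats, scope="genes_star",
        promoter_len=params["promoter_len"], genome=genome,
    )

    if "landscape" in stages:
        stats = feature_methylation_stats(sites, classes, genome)
        tables["class_stats"] = pd.DataFrame(
            [
                {
                    "class": s.class_name,
                    "n_fragments": s.n_fragments,
                    "n_fragments_methylated": s.n_fragments_methylated,
                    "frac_fragments_methylated": s.frac_fragments_methylated,
                    "n_adenines": s.n_adenines,
                    "n_6mA": s.n_6ma,
                    "density_6mA_per_A": s.density_6ma_per_a,
                }
                for s in stats.values()
            ]
        )
        gaps = intersite_intervals(sites)
        hotspots = call_hotspots(
            sites, min_sites=params["min_sites"], gap_max=params["gap_max"]
        )
        annotate_hotspot_te_overlap(hotspots, repeats)
        tables["hotspots"] = pd.DataFrame(
            [
                {
                    "chrom": h.chrom,
                    "start": h.start,
                    "end": h.end,
                    "n_sites": h.n_sites,
                    "max_gap": h.max_gap,
                    "overlaps_te": h.overlaps_te,
                }
                for h in hotspots
            ],
            columns=["chrom", "start", "end", "n_sites", "max_gap", "overlaps_te"],
        )
        write_hotspots_bed(hotspots, os.path.join(outdir, "hotspots.bed"))
        perm = None
        if hotspots and any(r.repeat_class == "TE" for r in repeats):
            perm = hotspot_te_permutation(
                hotspots, repeats, genome,
                n_perm=params["n_perm"], seed=params["seed"] + 11,
            )
        ctx = context_stats(sites, genome)
        tables["context_logo"] = pd.DataFrame(
            ctx.position_counts,
            columns=["A", "C", "G", "T"],
        ).assign(offset=np.arange(-ctx.flank, ctx.flank + 1))
        tables["motif_hits"] = pd.DataFrame(
            [
                {
                    "motif": m.motif,
                    "a_index": m.a_index,
                    "n_sites_matching": m.n_sites_matching,
                    "frac_sites_matching": m.frac_sites_matching,
                    "background_frac": m.background_frac,
                    "enrichment": m.enrichment,
                }
                for m in ctx.motif_hits
            ]
        )
        total_a = sum(
            int((genome.array(c) == ord("A")).sum() + (genome.array(c) == ord("T")).sum())
            for c in genome.chrom_ids
        )
        report["landscape"] = {
            "n_sites": len(sites),
            "global_density_6mA_per_A": len(sites) / total_a,
            "frac_intervals_below_2kb": gaps.fraction_below(2000),
            "n_hotspots": len(hotspots),
            "frac_sites_in_hotspots": (
                sum(h.n_sites for h in hotspots) / len(sites) if sites else None
            ),
            "hotspot_te_observed": perm.observed_fraction if perm else None,
            "hotspot_te_null_mean": perm.null_mean if perm else None,
            "hotspot_te_p": perm.p_value if perm else None,
            "motif_enrichment": {
                m.motif: m.enrichment for m in ctx.motif_hits
            },
        }

    if "metagene" in stages:
        body = gene_body_profile(genes, sites, grid=params["grid"])
        body_sm = body.smoothed(params["lowess_f"])
        tables["profile_gene_body"] = _profile_table(body, "occupancy").assign(
            smoothed=body_sm.values
        )
        with_introns = [g for g in genes if g.introns]
        if with_introns:
            intr = intron_profile(genes, sites, grid=params["intron_grid"])
            tables["profile_intron"] = _profile_table(intr, "occupancy")
        w = params["window"]
        tss = window_profile(
            [(g.chrom, g.tss, g.strand) for g in genes], sites, w, w, genome=genome
        )
        tts = window_profile(
            [(g.chrom, g.tts, g.strand) for g in genes], sites, w, w, genome=genome
        )
        tss_sm, tts_sm = tss.smoothed(params["lowess_f"]), tts.smoothed(params["lowess_f"])
        tables["profile_tss"] = pd.DataFrame(
            {"offset": np.arange(-w, w + 1), "occupancy": tss.values,
             "smoothed": tss_sm.values}
        )
        tables["profile_tts"] = pd.DataFrame(
            {"offset": np.arange(-w, w + 1), "occupancy": tts.values,
             "smoothed": tts_sm.values}
        )
        donor = None
        if with_introns:
            donor = donor_offset_profile(genes, sites, w=params["donor_w"])
            tables["donor_offsets"] = pd.DataFrame(
                {"offset": donor.offsets, "count": donor.counts,
                 "enrichment": donor.enrichment}
            )
        report["metagene"] = {
            "tts_peak_offset": int(np.argmax(tts_sm.values) - w),
            "tss_max_offset": int(np.argmax(tss_sm.values) - w),
            "donor_max_offset": (
                int(donor.offsets[int(np.argmax(donor.counts))]) if donor is not None else None
            ),
            "donor_max_enrichment": (
                float(donor.enrichment.max()) if donor is not None else None
            ),
        }

    if "associate" in stages and expression is not None:
        summaries = summarize_gene_methylation(
            genes, sites, genome, repeats, teg,
            promoter_len=params["promoter_len"],
            tss_window=(params["tss_window_up"], params["tss_window_down"]),
            tts_window=params["tts_window"],
            strand_policy=params["strand_policy"],
        )
        tables["gene_summaries"] = pd.DataFrame(
            [
                {
                    "gene_id": s.gene_id,
                    "body_count": s.body_count,
                    "body_density": s.body_density,
                    "promoter_count": s.promoter_count,
                    "tss_window_count": s.tss_window_count,
                    "tts_window_count": s.tts_window_count,
                    "utr3_count": s.utr3_count,
                    "te_count": s.te_count,
                    "promoter_body_class": s.promoter_body_class,
                }
                for s in summaries.values()
            ]
        )
        bins, n_unmatched = tpm_bin_fractions(summaries, expression)
        tables["tpm_bins"] = pd.DataFrame(
            [
                {"class": k, "bin": lbl, "fraction": v[i] if v else None}
                for k, v in bins.items()
                for i, lbl in enumerate(("<=1", "1-5", "5-10", ">=10"))
            ]
        )
        try:
            high, low, ratio, cmp_hl = occupancy_by_expression(
                genes, sites, expression, threshold=params["high_tpm"],
                grid=params["grid"],
            )
            tables["profile_body_by_expression"] = pd.DataFrame(
                {"grid_index": np.arange(high.grid_length),
                 "high": high.values, "low": low.values}
            )
        except ValueError:
            logger.warning("one expression stratum is empty; high/low contrast skipped")
            ratio, cmp_hl = None, None
        mean_tpm, comparisons = class_expression_table(
            summaries, expression, teg, active_tpm=params["active_tpm"]
        )
        tables["class_expression"] = pd.DataFrame(
            [
                {"teg_status": k[0], "class": k[1], "n_genes": v[0], "mean_tpm": v[1]}
                for k, v in sorted(mean_tpm.items())
            ]
        )
        tables["comparisons"] = pd.DataFrame(
            [
                {
                    "group_a": c.group_a, "group_b": c.group_b,
                    "n_a": c.n_a, "n_b": c.n_b,
                    "U": c.statistic, "p": c.p_value, "p_adjusted": c.p_adjusted,
                    "direction": c.direction,
                }
                for c in comparisons
            ]
        )
        gene_plus = [
            e.tpm_mean for e in expression
            if e.gene_id in summaries and summaries[e.gene_id].gene_plus
        ]
        gene_minus = [
            e.tpm_mean for e in expression
            if e.gene_id in summaries and not summaries[e.gene_id].gene_plus
        ]
        from .expression import compare_groups

        gp = (
            compare_groups(gene_plus, gene_minus, group_a="Gene+", group_b="Gene-")
            if gene_plus and gene_minus
            else None
        )
        report["associate"] = {
            "n_genes_with_expression": len(expression) - n_unmatched,
            "high_low_body_count_excess": ratio,
            "high_low_p": cmp_hl.p_value if cmp_hl else None,
            "gene_plus_vs_minus_p": gp.p_value if gp else None,
            "gene_plus_fraction": (
                len(gene_plus) / (len(gene_plus) + len(gene_minus))
                if gene_plus or gene_minus
                else None
            ),
        }

    if "diffmeth" in stages and params.get("wt_sites") and params.get("mut_sites"):
        def load_reps(paths, genotype):
            reps = []
            for i, p in enumerate(paths):
                s = read_methylation_sites(
                    p, genome, min_fraction=params.get("mutant_min_fraction", 0.1)
                )
                reps.append(
                    SampleMethylome(
                        sample_id=f"{genotype}_{i + 1}",
                        genotype=genotype,
                        replicate=str(i + 1),
                        sites=s,
                        _genome=genome,
                    )
                )
            return reps

        wt_reps = load_reps(params["wt_sites"], "WT")
        mut_reps = load_reps(params["mut_sites"], "mutant")
        pct, p = global_shift(wt_reps, mut_reps, unit=params.get("unit", "chromosome"))
        records, summary = gene_level_diff(
            wt_reps, mut_reps, genes, genome,
            fc_up=params["fc_up"], fc_down=params["fc_down"],
        )
        tables["diffmeth"] = pd.DataFrame(
            [
                {
                    "gene_id": r.gene_id,
                    "marked_all_wt": r.marked_all_wt,
                    "marked_all_mut": r.marked_all_mut,
                    "level_wt": r.level_wt,
                    "level_mut": r.level_mut,
                    "fold_change": r.fold_change,
                    "fc_category": r.fc_category(params["fc_up"], params["fc_down"]),
                    "state_change": r.state_change,
                }
                for r in records
            ]
        )
        overlay = overlay_deg(records, degs) if degs else None
        if overlay is not None:
            tables["overlay"] = pd.DataFrame(
                [
                    {"deg_direction": d, "fc_category": f, "n": overlay.cell(d, f)}
                    for d in ("up", "down")
                    for f in ("up", "down", "stable")
                ]
            )
        report["diffmeth"] = {
            "global_shift_percent": pct,
            "global_shift_p": p,
            "n_union_marked": summary.n_union,
            "frac_shared": summary.frac_shared,
            "frac_shared_fc_changed": summary.frac_shared_fc_changed,
            "frac_to_none": summary.frac_to_none,
            "frac_from_none": summary.frac_from_none,
            "overlay": (
                {f"{d}_{f}": overlay.cell(d, f)
                 for d in ("up", "down") for f in ("up", "down", "stable")}
                if overlay
                else None
            ),
        }

    if "enrich" in stages and params.get("cog_map"):
        from .enrichment import cog_table

        cog_df = pd.read_csv(params["cog_map"], sep="\t")
        cog_map = dict(zip(cog_df.iloc[:, 0].astype(str), cog_df.iloc[:, 1].astype(str)))
        summaries = summarize_gene_methylation(
            genes, sites, genome, repeats, teg,
            promoter_len=params["promoter_len"],
        )
        res = cog_table(summaries, cog_map, genes)
        tables["cog_enrichment"] = pd.DataFrame(
            [
                {
                    "category": c.category,
                    "n_genes": c.n_genes,
                    "n_methylated": c.n_methylated,
                    "frac": c.frac,
                    "background_frac": c.background_frac,
                    "p_raw": c.p_raw,
                    "p_adjusted": c.p_adjusted,
                    "mean_gene_length": c.mean_gene_length,
                    "density": c.density,
                }
                for c in res.categories
            ]
        )
        report["enrich"] = {
            "n_categories": len(res.categories),
            "length_frac_pearson_r": res.length_frac_pearson_r,
            "length_frac_pearson_p": res.length_frac_pearson_p,
            "density_outlier": (
                res.density_grubbs.has_outlier if res.density_grubbs else None
            ),
        }

    manifest = {
        "inputs": {
            k: {"path": params[k], "sha256": _sha256(params[k])}
            for k in ("genome", "genes", "repeats", "sites", "expression", "degs")
            if params.get(k) and isinstance(params[k], str) and os.path.exists(params[k])
        },
        "parameters": {k: v for k, v in params.items() if not isinstance(v, (list, dict))},
        "defaults_used": defaults_used,
        "seed": params["seed"],
        "stages": list(stages),
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "tables": sorted(tables),
    }
    write_results(tables, outdir, manifest=manifest)
    with open(os.path.join(outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
    return report
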
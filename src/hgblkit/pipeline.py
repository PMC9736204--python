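"""Top-level pipeline: FISH classification -> variant filtering -> CNA/MCR ->
integration -> group comparison -> survival.

``write_cohort`` serialises a synthetic bundle to the on-disk interchange
formats; ``run_pipeline`` consumes such a directory (or real data in the
same layout) and writes all stage outputs plus a JSON report with per-stage
counts. Any stage failure raises :class:`PipelineStageError` tagged with the
stage name; the CLI converts that into a non-zero exit code.
"""

from __future__ import annotations

import json
import os
from typing import Dict, List, Optional

import pandas as pd

from . import cna, fish, io, stats, variants
from .synthetic import CohortBundle, CohortConfig, default_cytobands, DEFAULT_BCL6_EXONS

__all__ = ["PipelineStageError", "write_cohort", "run_pipeline"]

ANALYSIS_GROUPS = {"DHL": "DHL_THL", "THL": "DHL_THL", "SHL": "SHL", "MCAD": "MCAD"}


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def write_cohort(bundle: CohortBundle, config: CohortConfig, outdir: str) -> None:
    """Write a cohort bundle to disk in the interchange formats."""
    os.makedirs(outdir, exist_ok=True)
    vcf_dir = os.path.join(outdir, "vcf")
    os.makedirs(vcf_dir, exist_ok=True)
    for sample, per_caller in sorted(bundle.caller_calls.items()):
        for k, calls in enumerate(per_caller):
            io.write_vcf(
                calls,
                os.path.join(vcf_dir, f"{sample}.caller{k}.vcf"),
                genome=config.genome,
            )
    io.write_seg(bundle.segments, os.path.join(outdir, "segments.seg"))
    io.write_table(bundle.fish, os.path.join(outdir, "fish.tsv"))
    io.write_table(bundle.clinical, os.path.join(outdir, "clinical.tsv"))
    io.write_truth(bundle.truth, os.path.join(outdir, "truth.json"))
    with open(os.path.join(outdir, "panel.txt"), "w") as fh:
        fh.write("\n".join(config.panel) + "\n")
    bcl6_chrom = "chr3"
    io.write_bed(
        [(bcl6_chrom, s, e, f"BCL6_exon{i + 3}") for i, (s, e) in enumerate(DEFAULT_BCL6_EXONS)],
        os.path.join(outdir, "bcl6_exons.bed"),
    )
    io.write_cytoband(default_cytobands(), os.path.join(outdir, "cytoband.txt"))
    genome_df = pd.DataFrame(config.genome, columns=["chrom", "length"])
    io.write_table(genome_df, os.path.join(outdir, "genome.tsv"))


def _load_caller_vcfs(vcf_dir: str, caller_count: int):
    """Group VCF files named ``<sample>.caller<k>.vcf`` by sample."""
    per_sample: Dict[str, List[Optional[str]]] = {}
    for name in sorted(os.listdir(vcf_dir)):
        if not name.endswith(".vcf"):
            continue
        stem = name[: -len(".vcf")]
        sample, _, caller = stem.rpartition(".caller")
        if not sample or not caller.isdigit():
            continue
        per_sample.setdefault(sample, [None] * caller_count)
        per_sample[sample][int(caller)] = os.path.join(vcf_dir, name)
    return per_sample


def run_pipeline(config: io.PipelineConfig) -> dict:
    """Execute all stages on an input directory; returns the JSON report."""
    config.validate()
    indir, outdir = config.input_dir, config.output_dir
    os.makedirs(outdir, exist_ok=True)
    log = io.get_logger()
    log.info("pipeline start: seed=%s thresholds=%s", config.seed, {
        "min_callers": config.min_callers, "af_snp": config.af_snp,
        "af_likely": config.af_likely, "fish_threshold": config.fish_threshold,
        "gain_log2": config.gain_log2, "loss_log2": config.loss_log2,
        "min_freq": config.min_freq, "bin_size": config.bin_size,
        "alpha": config.alpha,
    })
    report: dict = {"stages": {}, "seed": config.seed}

    # ---------------- classify-fish ----------------
    stage = "classify-fish"
    try:
        fish_df = io.read_table(os.path.join(indir, "fish.tsv"))
        clinical = io.read_table(os.path.join(indir, "clinical.tsv"))
        cases = fish.classify_fish_table(
            fish_df,
            ihc=clinical.rename(columns={"case": "case_id"})
            if "cd10_pct" in clinical.columns
            else None,
            threshold=config.fish_threshold,
            min_cells=config.fish_min_cells,
        )
        cases["group"] = cases["subtype"].map(ANALYSIS_GROUPS).fillna("NOT_CLASSIFIED")
        io.write_table(cases, os.path.join(outdir, "cases.tsv"))
        report["stages"][stage] = {
            "n_cases": int(len(cases)),
            "subtypes": cases["subtype"].value_counts().to_dict(),
        }
    except Exception as err:
        raise PipelineStageError(stage, str(err)) from err

    groups = dict(zip(cases["case_id"], cases["group"]))

    # ---------------- call-filter ----------------
    stage = "call-filter"
    try:
        panel_path = config.panel_path or os.path.join(indir, "panel.txt")
        with open(panel_path) as fh:
            panel = [line.strip() for line in fh if line.strip()]
        bed_path = config.bcl6_exons_path or os.path.join(indir, "bcl6_exons.bed")
        bcl6_exons = None
        if os.path.exists(bed_path):
            bed = io.read_bed(bed_path)
            bcl6_exons = list(zip(bed["start"], bed["end"]))
        per_sample = _load_caller_vcfs(
            os.path.join(indir, "vcf"), config.caller_count
        )
        mutation_rows = []
        burden_rows = []
        selected_all: Dict[str, list] = {}
        for sample in sorted(per_sample):
            lists = [
                io.read_vcf(p, sample_id=sample, caller_index=k,
                            caller_count=config.caller_count)
                if p is not None else []
                for k, p in enumerate(per_sample[sample])
            ]
            merged = variants.merge_caller_calls(lists, config.caller_count)
            confident = variants.consensus_filter(merged, config.min_callers)
            masked = variants.apply_bcl6_exon_mask(confident, bcl6_exons)
            classified = variants.classify_variants(
                masked, af_snp=config.af_snp, af_likely=config.af_likely
            )
            selected = variants.select_mutations(classified)
            selected_all[sample] = selected
            rec = variants.mutation_burden(selected, panel)
            burden_rows.append(
                {"sample": sample, "burden": rec.burden,
                 "mutated_genes": ",".join(sorted(rec.mutated_genes))}
            )
            for m in selected:
                mutation_rows.append(
                    {"sample": sample, "gene": m.gene, "chrom": m.chrom,
                     "pos": m.pos, "ref": m.ref, "alt": m.alt,
                     "consequence": m.consequence,
                     "caller_count": m.caller_count, "category": m.category}
                )
        mutations_df = pd.DataFrame(
            mutation_rows,
            columns=["sample", "gene", "chrom", "pos", "ref", "alt",
                     "consequence", "caller_count", "category"],
        )
        burden_df = pd.DataFrame(burden_rows, columns=["sample", "burden", "mutated_genes"])
        io.write_table(mutations_df, os.path.join(outdir, "mutations.tsv"))
        io.write_table(burden_df, os.path.join(outdir, "burden.tsv"))
        freq_rows = []
        all_selected = [m for sel in selected_all.values() for m in sel]
        for group_label in sorted(set(groups.values())):
            members = [s for s, g in groups.items() if g == group_label]
            if not members:
                continue
            freq = variants.cohort_gene_frequency(all_selected, members)
            for gene, (k, n, frac) in freq.items():
                freq_rows.append(
                    {"group": group_label, "gene": gene, "mutated": k,
                     "n": n, "fraction": frac,
                     "display_pct": round(100 * frac)}
                )
        io.write_table(
            pd.DataFrame(freq_rows,
                         columns=["group", "gene", "mutated", "n",
                                  "fraction", "display_pct"]),
            os.path.join(outdir, "gene_frequency.tsv"),
        )
        report["stages"][stage] = {
            "n_samples": len(per_sample),
            "n_selected_mutations": int(len(mutations_df)),
            "mean_burden": float(burden_df["burden"].mean()) if len(burden_df) else 0.0,
        }
    except PipelineStageError:
        raise
    except Exception as err:
        raise PipelineStageError(stage, str(err)) from err

    # ---------------- cna-mcr ----------------
    stage = "cna-mcr"
    try:
        segments = io.read_seg(os.path.join(indir, "segments.seg"))
        calls = cna.call_cna_states(
            segments, gain_log2=config.gain_log2, loss_log2=config.loss_log2
        )
        cyto_path = config.cytoband_path or os.path.join(indir, "cytoband.txt")
        cytobands = io.read_cytoband(cyto_path) if os.path.exists(cyto_path) else None
        genome_path = os.path.join(indir, "genome.tsv")
        if os.path.exists(genome_path):
            genome_df = io.read_table(genome_path)
            genome = list(zip(genome_df["chrom"], genome_df["length"]))
        else:
            genome = [
                (c, int(g["end"].max()))
                for c, g in segments.groupby("chrom", sort=True)
            ]
        bins = cna.bin_genome(genome, config.bin_size)
        mcr_rows = []
        for group_label in sorted(set(groups.values())):
            members = [s for s, g in groups.items() if g == group_label]
            members = [s for s in members if s in set(calls["sample"])]
            if not members:
                continue
            for direction in cna.DIRECTIONS:
                for r in cna.find_mcrs(
                    calls, direction, min_freq=config.min_freq,
                    group_samples=members, cytobands=cytobands,
                ):
                    mcr_rows.append({"group": group_label, **r.__dict__})
        mcr_df = pd.DataFrame(
            mcr_rows,
            columns=["group", "chrom", "start", "end", "direction",
                     "frequency", "n_samples", "cytoband_label", "is_peak"],
        )
        io.write_table(mcr_df, os.path.join(outdir, "mcr.tsv"))
        freq_pieces = []
        for group_label in sorted(set(groups.values())):
            members = [s for s, g in groups.items()
                       if g == group_label and s in set(calls["sample"])]
            if not members:
                continue
            for direction in cna.DIRECTIONS:
                f = cna.alteration_frequency(calls, bins, members, direction)
                f.insert(0, "group", group_label)
                freq_pieces.append(f)
        io.write_table(
            pd.concat(freq_pieces, ignore_index=True)
            if freq_pieces else pd.DataFrame(),
            os.path.join(outdir, "binned_frequency.tsv"),
        )
        cmp_df = pd.DataFrame()
        regions_df = pd.DataFrame()
        a_members = [s for s, g in groups.items() if g == "DHL_THL"]
        b_members = [s for s, g in groups.items() if g == "SHL"]
        if a_members and b_members:
            per_bin, regions_df = cna.compare_cna_groups(
                calls[calls["sample"].isin(a_members)],
                calls[calls["sample"].isin(b_members)],
                bins, alpha=config.alpha,
            )
            cmp_df = per_bin
        io.write_table(cmp_df, os.path.join(outdir, "cna_group_comparison.tsv"))
        io.write_table(regions_df, os.path.join(outdir, "cna_significant_regions.tsv"))
        report["stages"][stage] = {
            "n_segments": int(len(segments)),
            "n_mcrs": int(len(mcr_df)),
            "n_significant_bins": int((cmp_df["p"] < config.alpha).sum())
            if len(cmp_df) else 0,
        }
    except PipelineStageError:
        raise
    except Exception as err:
        raise PipelineStageError(stage, str(err)) from err

    # ---------------- integrate ----------------
    stage = "integrate"
    try:
        from .synthetic import default_gene_map

        gene_map = default_gene_map(panel, genome)
        gene_cna = stats.gene_level_cna(calls, gene_map)
        samples = sorted(groups)
        matrix = stats.build_alteration_matrix(
            all_selected, gene_cna, panel, samples, groups
        )
        matrix_out = matrix.status.copy()
        matrix_out.insert(0, "gene", matrix_out.index)
        io.write_table(matrix_out, os.path.join(outdir, "alteration_matrix.tsv"))
        n_altered = int((matrix.status != "none").to_numpy().sum())
        report["stages"][stage] = {
            "n_genes": int(matrix.status.shape[0]),
            "n_samples": int(matrix.status.shape[1]),
            "n_altered_cells": n_altered,
        }
    except PipelineStageError:
        raise
    except Exception as err:
        raise PipelineStageError(stage, str(err)) from err

    # ---------------- compare ----------------
    stage = "compare"
    try:
        cmp_rows = pd.DataFrame()
        burden_p = None
        if a_members and b_members:
            cmp_rows = stats.compare_mutation_frequencies(matrix, "DHL_THL", "SHL")
            bmap = dict(zip(burden_df["sample"], burden_df["burden"]))
            xa = [bmap[s] for s in a_members if s in bmap]
            xb = [bmap[s] for s in b_members if s in bmap]
            if xa and xb:
                _, burden_p = stats.mann_whitney_u(xa, xb)
        io.write_table(cmp_rows, os.path.join(outdir, "mutation_comparison.tsv"))
        report["stages"][stage] = {
            "n_genes_compared": int(len(cmp_rows)),
            "burden_mannwhitney_p": burden_p,
        }
    except PipelineStageError:
        raise
    except Exception as err:
        raise PipelineStageError(stage, str(err)) from err

    # ---------------- survival ----------------
    stage = "survival"
    try:
        clin = clinical.copy()
        clin["prognosis"] = [
            stats.assign_prognosis_group(r, bool(rel))
            for r, rel in zip(clin["first_course_response"], clin["relapse"])
        ]
        surv: dict = {"groups": {}}
        curves = {}
        for label, sub in clin.groupby("prognosis"):
            km = stats.km_curve(sub["os_time"], sub["os_event"].astype(bool))
            curves[label] = km
            surv["groups"][label] = {
                "n": int(len(sub)),
                "events": int(sub["os_event"].sum()),
                "km": km.to_dict(orient="list"),
            }
        if len(curves) >= 2:
            chi2, p = stats.logrank_test(
                [
                    (sub["os_time"].tolist(),
                     sub["os_event"].astype(bool).tolist())
                    for _, sub in clin.groupby("prognosis")
                ]
            )
            surv["logrank"] = {"chi2": chi2, "p": p}
        with open(os.path.join(outdir, "survival.json"), "w") as fh:
            json.dump(surv, fh, indent=1, sort_keys=True)
        report["stages"][stage] = {
            "n_cases": int(len(clin)),
            "favorable": int((clin["prognosis"] == "favorable").sum()),
            "adverse": int((clin["prognosis"] == "adverse").sum()),
        }
    except PipelineStageError:
        raise
    except Exception as err:
        raise PipelineStageError(stage, str(err)) from err

    with open(os.path.join(outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    log.info("pipeline complete: %s", {k: v for k, v in report["stages"].items()})
    return report
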
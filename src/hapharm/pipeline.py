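"""End-to-end orchestration: pedigree -> blocks -> alleles -> scan ->
audit -> segregation -> overlaps, with a JSON report and Markdown summary.

The pipeline is deterministic given fixed inputs: rerunning on the same
files reproduces the same report (timestamps excluded by design — none
are written).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import alleles as alleles_mod
from . import candidates as cand_mod
from . import mendel, overlap, segregation, vcfio
from .blocks import (
    LinkageBlockDef,
    blocks_to_frame,
    detect_blocks,
    read_plink_blocks,
    write_block_bed,
    write_plink_blocks,
)
from .pedigree import (
    assign_cohorts,
    enumerate_families,
    equivalent_complete_generations,
    load_pedigree,
    write_cohort_table,
)

__all__ = ["PipelineConfig", "run_pipeline", "make_report", "read_block_bed"]


@dataclass
class PipelineConfig:
    """Inputs and knobs for one pipeline run.

    Exactly one genotype source is required: a phased VCF (blocks are then
    detected, or read from ``plink_blocks``) or a precoded block-genotype
    TSV accompanied by a block BED.  ``bp_ids`` defaults to the pedigree
    founders when empty.
    """

    pedigree_csv: str
    outdir: str
    vcf: str | None = None
    block_genotypes: str | None = None
    blocks_bed: str | None = None
    plink_blocks: str | None = None
    rho_windows: str | None = None
    cnv_bed: str | None = None
    bp_ids: tuple[str, ...] = ()
    keep_ids: tuple[str, ...] = ()
    min_offspring: int = 5
    alpha: float = 0.05
    direction: str = "rare"
    max_span_kb: float = 400.0
    informative_fraction: float = 0.95
    ci_thresholds: tuple[float, float, float] = (0.98, 0.70, 0.90)
    k_sd: float = 2.5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("bp_ids", "keep_ids", "ci_thresholds"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def read_block_bed(path: str | Path) -> list[LinkageBlockDef]:
    """Block definitions from a BED file (0-based half-open -> 1-based)."""
    out = []
    for iv in overlap.read_bed(path):
        out.append(
            LinkageBlockDef(
                block_id=iv.label or f"LB{len(out) + 1}",
                chrom=iv.chrom,
                start_bp=iv.start + 1,
                end_bp=iv.end,
            )
        )
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write all outputs under ``config.outdir``.

    Returns the report dict (also written as ``report.json``).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- pedigree and cohorts ---------------------------------------------
    ped = load_pedigree(config.pedigree_csv)
    t_map = equivalent_complete_generations(ped)
    bp_ids = tuple(config.bp_ids) or ped.founders()
    cohorts = assign_cohorts(t_map, bp_ids)
    write_cohort_table(cohorts, outdir / "cohorts.tsv")
    families = enumerate_families(
        ped, min_offspring=config.min_offspring, keep_ids=config.keep_ids
    )

    # --- genotypes and blocks ---------------------------------------------
    registry = None
    if config.vcf is not None:
        snps, hap, samples = vcfio.read_phased_vcf(config.vcf)
        if config.plink_blocks is not None:
            blocks = read_plink_blocks(config.plink_blocks, snps)
        else:
            blocks = detect_blocks(
                hap,
                snps,
                max_span_kb=config.max_span_kb,
                informative_fraction=config.informative_fraction,
                thresholds=config.ci_thresholds,
            )
        registry, genotypes = alleles_mod.code_block_haplotypes(hap, blocks, samples)
        write_plink_blocks(blocks, snps, outdir / "blocks.det")
        registry.to_csv(outdir / "allele_registry.tsv", sep="\t", index=False)
    elif config.block_genotypes is not None:
        from .simulate import read_block_genotypes

        genotypes = read_block_genotypes(config.block_genotypes)
        if config.blocks_bed is None:
            raise ValueError("block_genotypes input requires blocks_bed")
        blocks = read_block_bed(config.blocks_bed)
    else:
        raise ValueError("need either a VCF or a block-genotype table")
    write_block_bed(blocks, outdir / "blocks.bed")

    cohorts = cohorts[cohorts["id"].isin(set(genotypes["individual"]))]

    # --- allele statistics and candidate scan ------------------------------
    stats = alleles_mod.compute_scope_stats(genotypes, cohorts)
    calls = {
        scope: cand_mod.classify_candidates(df, config.alpha, config.direction)
        for scope, df in stats.items()
    }
    pd.concat(calls.values()).to_csv(
        outdir / "candidate_calls.tsv", sep="\t", index=False
    )
    scan_summary = cand_mod.cross_scope_comparison(calls)
    private = alleles_mod.cohort_private_alleles(stats)
    private.to_csv(outdir / "private_alleles.tsv", sep="\t", index=False)

    # --- Mendelian audit ----------------------------------------------------
    mismatches, rates, tallies = mendel.audit_population(
        genotypes, ped, cohorts=cohorts, families=families
    )
    mismatches.to_csv(outdir / "mismatches.tsv", sep="\t", index=False)
    fam_summary = mendel.family_size_summary(mismatches, families)
    fam_summary.to_csv(outdir / "family_summary.tsv", sep="\t", index=False)
    rates_dict = {
        "m_a": rates.m_a,
        "m_l": rates.m_l,
        "nt": rates.nt,
        "e_a": rates.e_a,
        "e_l": rates.e_l,
        "lb_fraction": rates.lb_fraction,
        "by_attribution": tallies.get("by_attribution", {}),
    }
    (outdir / "error_rates.json").write_text(json.dumps(rates_dict, indent=1))

    # --- segregation classification of WP candidates ------------------------
    wp_calls = calls["WP"]
    wp_cand = wp_calls[wp_calls["is_candidate"]]
    presences = segregation.trace_alleles(wp_cand, genotypes, ped)
    presences.to_csv(outdir / "segregation.tsv", sep="\t", index=False)
    venn = segregation.venn_table(presences)
    (outdir / "venn.json").write_text(json.dumps(venn, indent=1))
    class_counts = (
        presences["segregation_class"].value_counts().to_dict()
        if len(presences)
        else {}
    )

    # --- interval overlaps ---------------------------------------------------
    overlap_section = None
    if config.rho_windows is not None or config.cnv_bed is not None:
        hot: list[overlap.GenomicInterval] = []
        if config.rho_windows is not None:
            windows = overlap.read_rho_windows(config.rho_windows)
            hs = overlap.detect_hotspots(windows, k_sd=config.k_sd)
            hot = [
                overlap.GenomicInterval(r.chrom, int(r.start), int(r.end), "hotspot")
                for r in hs.itertuples(index=False)
            ]
        cnvs = overlap.read_bed(config.cnv_bed) if config.cnv_bed else []
        overlap_section = overlap.overlap_summary(
            blocks, hot, cnvs, allele_stats=stats["WP"], genotypes=genotypes
        )
        (outdir / "overlap.json").write_text(json.dumps(overlap_section, indent=1))

    # --- report --------------------------------------------------------------
    report = {
        "n_individuals": int(cohorts["id"].nunique()),
        "cohort_sizes": cohorts["cohort"].value_counts().to_dict(),
        "n_families": len(families),
        "n_blocks": len(blocks),
        "observed_homozygosity": alleles_mod.observed_homozygosity(genotypes),
        "alleles_per_scope": {s: int(len(df)) for s, df in stats.items()},
        "candidate_scan": scan_summary,
        "private_alleles": int(len(private)),
        "error_rates": rates_dict,
        "segregation_classes": class_counts,
        "venn": venn,
        "overlap": overlap_section,
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=1, default=int))
    (outdir / "report.md").write_text(
        make_report(report, blocks, stats.get("WP"), presences, genotypes)
    )
    return report


def make_report(
    report: dict,
    blocks: list[LinkageBlockDef],
    wp_stats: pd.DataFrame | None = None,
    presences: pd.DataFrame | None = None,
    genotypes: pd.DataFrame | None = None,
) -> str:
    """Human-readable Markdown summary of a pipeline run.

    Includes a per-chromosome block table (count, mean length, mean
    alleles per block) and, when segregant candidates exist, a per-block
    segregant table with coordinates and ``length = end - start``.
    """
    lines = ["# hapharm report", ""]
    lines.append(f"Individuals analyzed: {report['n_individuals']}")
    lines.append(f"Linkage blocks: {report['n_blocks']}")
    lines.append(
        f"Observed homozygosity: {report['observed_homozygosity']:.3f}"
    )
    lines.append("")

    # per-chromosome block summary
    frame = blocks_to_frame(blocks)
    if len(frame):
        alleles_per_block = None
        if wp_stats is not None and len(wp_stats):
            alleles_per_block = wp_stats.groupby("block_id").size()
        lines += ["## Blocks per chromosome", ""]
        lines.append("| Chrom | Blocks | Mean length (kb) | Mean alleles |")
        lines.append("|---|---|---|---|")
        for chrom, grp in frame.groupby("chrom", sort=False):
            if alleles_per_block is not None:
                mean_alleles = alleles_per_block.reindex(grp["block_id"]).mean()
            else:
                mean_alleles = float("nan")
            lines.append(
                f"| {chrom} | {len(grp)} | {grp['length_bp'].mean() / 1000:.1f} "
                f"| {mean_alleles:.1f} |"
            )
        lines.append("")

    scan = report.get("candidate_scan", {})
    if scan:
        lines += ["## Candidate alleles per scope", ""]
        lines.append("| Scope | Alleles | Candidates | Candidate blocks |")
        lines.append("|---|---|---|---|")
        for scope, entry in scan.get("scopes", {}).items():
            lines.append(
                f"| {scope} | {entry['total_alleles']} | {entry['candidates']} "
                f"| {entry['candidate_blocks']} |"
            )
        lines.append("")

    err = report.get("error_rates", {})
    if err:
        lines += [
            "## Parent-offspring inconsistencies",
            "",
            f"- allelic mismatches (m_a): {err['m_a']}",
            f"- genotypes with >=1 mismatch (m_l): {err['m_l']}",
            f"- error rate per allele (e_a): {err['e_a']:.4f}",
            f"- error rate per locus (e_l): {err['e_l']:.4f}",
            f"- fraction of blocks with >=1 mismatch: {err['lb_fraction']:.4f}",
            "",
        ]

    classes = report.get("segregation_classes", {})
    lines += ["## Segregation classes of candidate alleles", ""]
    if classes:
        for label in segregation.SEGREGATION_CLASSES:
            lines.append(f"- {label}: {classes.get(label, 0)}")
    else:
        lines.append("Zero candidate alleles; nothing to classify.")
    lines.append("")

    if presences is not None and len(presences):
        seg = presences[presences["segregation_class"] == "segregant"]
        if len(seg):
            by_id = {b.block_id: b for b in blocks}
            hom = None
            if genotypes is not None:
                hom = (
                    genotypes[genotypes["allele1"] == genotypes["allele2"]]
                    .groupby("block_id")
                    .size()
                )
            lines += ["## Segregant candidate blocks", ""]
            lines.append(
                "| Block | Chrom | Start (bp) | End (bp) | Length (bp) | Homozygous |"
            )
            lines.append("|---|---|---|---|---|---|")
            for bid in sorted(seg["block_id"].unique()):
                blk = by_id[bid]
                h = int(hom.get(bid, 0)) if hom is not None else 0
                lines.append(
                    f"| {bid} | {blk.chrom} | {blk.start_bp} | {blk.end_bp} "
                    f"| {blk.length_bp} | {h} |"
                )
            lines.append("")
    return "\n".join(lines)
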
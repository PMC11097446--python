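"""Genomic interval work: recombination hotspots and CNV overlaps.

All intervals are 0-based half-open (BED convention); 1-based block
coordinates are converted on ingest with ``start - 1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .blocks import LinkageBlockDef

__all__ = [
    "GenomicInterval",
    "read_bed",
    "read_rho_windows",
    "detect_hotspots",
    "blocks_as_intervals",
    "intersect_blocks",
    "overlap_summary",
]


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open labelled interval."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.label or self.chrom}: end must exceed start")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3+ (chrom, start, end[, name])."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split()
            out.append(
                GenomicInterval(
                    chrom=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    label=f[3] if len(f) > 3 else "",
                )
            )
    return out


def read_rho_windows(path: str | Path) -> pd.DataFrame:
    """Read a recombination-rate window table: chrom, start, end, rho (TSV)."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "rho"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    if (df["rho"] < 0).any():
        raise ValueError("rho must be non-negative")
    return df


def detect_hotspots(
    windows: pd.DataFrame, k_sd: float = 2.5, per_chrom: bool = False
) -> pd.DataFrame:
    """Windows whose rho exceeds mean + k_sd standard deviations.

    The baseline is genome-wide by default (``per_chrom=True`` recomputes
    mean and s.d. within each chromosome).  The s.d. is the population
    standard deviation.  Scale-invariant: rescaling all rho by a positive
    constant leaves the hotspot set unchanged.
    """
    if len(windows) < 2:
        raise ValueError("need at least two windows")

    def _flag(df: pd.DataFrame) -> pd.Series:
        mu = df["rho"].mean()
        sd = df["rho"].std(ddof=0)
        return df["rho"] > mu + k_sd * sd

    if per_chrom:
        mask = windows.groupby("chrom", group_keys=False).apply(
            _flag, include_groups=False
        )
        mask = mask.reindex(windows.index)
    else:
        mask = _flag(windows)
    return windows[mask.to_numpy()]


def blocks_as_intervals(blocks: Sequence[LinkageBlockDef]) -> list[GenomicInterval]:
    """Blocks converted from 1-based inclusive to 0-based half-open."""
    return [
        GenomicInterval(b.chrom, b.start_bp - 1, b.end_bp, b.block_id)
        for b in blocks
    ]


def intersect_blocks(
    blocks: Sequence[GenomicInterval], intervals: Sequence[GenomicInterval]
) -> pd.DataFrame:
    """All (block, interval) pairs sharing >= 1 bp, with overlap length.

    Columns: ``block, interval, chrom, overlap_bp``.
    """
    trees: dict[str, IntervalTree] = {}
    for k, iv in enumerate(intervals):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, k)
    rows = []
    for blk in blocks:
        tree = trees.get(blk.chrom)
        if tree is None:
            continue
        for hit in sorted(tree.overlap(blk.start, blk.end)):
            iv = intervals[hit.data]
            rows.append(
                {
                    "block": blk.label,
                    "interval": iv.label,
                    "chrom": blk.chrom,
                    "overlap_bp": min(blk.end, iv.end) - max(blk.start, iv.start),
                }
            )
    return pd.DataFrame(rows, columns=["block", "interval", "chrom", "overlap_bp"])


def overlap_summary(
    blocks: Sequence[LinkageBlockDef],
    hotspots: Sequence[GenomicInterval],
    cnvs: Sequence[GenomicInterval],
    allele_stats: pd.DataFrame | None = None,
    genotypes: pd.DataFrame | None = None,
) -> dict:
    """Per-category block/allele tallies for hotspot and CNV overlaps.

    Categories: blocks overlapping hotspots only, CNVs only, or both
    (counted once in ``both``).  When ``allele_stats`` (a WP allele
    frame) is given, allele counts and mean alleles per block are added;
    with ``genotypes`` also the observed homozygosity over the category's
    blocks.
    """
    as_iv = blocks_as_intervals(blocks)
    hot_blocks = set(intersect_blocks(as_iv, list(hotspots))["block"])
    cnv_blocks = set(intersect_blocks(as_iv, list(cnvs))["block"])
    both = hot_blocks & cnv_blocks
    cats = {
        "hotspot_only": hot_blocks - both,
        "cnv_only": cnv_blocks - both,
        "both": both,
    }
    by_id = {b.block_id: b for b in blocks}
    out = {}
    for name, ids in cats.items():
        entry: dict = {
            "n_blocks": len(ids),
            "mean_length_bp": float(
                np.mean([by_id[i].length_bp for i in ids])
            )
            if ids
            else 0.0,
        }
        if allele_stats is not None:
            sub = allele_stats[allele_stats["block_id"].isin(ids)]
            n_alleles = int(len(sub[["block_id", "code"]].drop_duplicates()))
            entry["n_alleles"] = n_alleles
            entry["mean_alleles_per_block"] = n_alleles / len(ids) if ids else 0.0
        if genotypes is not None and ids:
            sub_g = genotypes[genotypes["block_id"].isin(ids)]
            entry["observed_homozygosity"] = float(
                (sub_g["allele1"] == sub_g["allele2"]).mean()
            ) if len(sub_g) else 0.0
        out[name] = entry
    return out
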
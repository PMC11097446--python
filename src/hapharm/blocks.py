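"""Haplotype-block detection from phased biallelic SNPs.

Blocks are called with the confidence-interval definition of Gabriel-style
haplotype blocks: for every SNP pair a one-sided likelihood profile of
``|D'|`` is computed on a fixed grid, the pair is classified as *strong LD*
or *strong evidence of historical recombination* from the bounds of that
profile, and maximal runs of SNPs whose pairwise classifications are
dominated by strong LD become blocks.  Because the input is phased,
haplotype counts are exact and no EM frequency estimation is needed.

A hard cap on the physical span of a block (default 400 kb, the average
extent of LD reported for pig) keeps blocks within the range where
haplotypes behave as single alleles.

Coordinate conventions: SNP positions are 1-based; a block's length is
``end_bp - start_bp``; BED output is 0-based half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SnpRecord",
    "PairClass",
    "LinkageBlockDef",
    "MonomorphicPairError",
    "pair_dprime_ci",
    "classify_pair",
    "compute_pair_classes",
    "find_blocks",
    "detect_blocks",
    "read_plink_blocks",
    "write_plink_blocks",
    "write_block_bed",
]

STRONG_LD = "strong_ld"
STRONG_RECOMB = "strong_recomb"
UNINFORMATIVE = "uninformative"


class MonomorphicPairError(ValueError):
    """Raised when a SNP in a pair is monomorphic in the sample."""


@dataclass(frozen=True)
class SnpRecord:
    """A mapped biallelic SNP (1-based position)."""

    chrom: str
    pos: int
    id: str
    ref: str = "A"
    alt: str = "B"

    def __post_init__(self) -> None:
        if self.pos <= 0:
            raise ValueError(f"SNP {self.id}: position must be positive")


@dataclass(frozen=True)
class PairClass:
    """D' point estimate, CI bounds and LD classification for a SNP pair."""

    i: int
    j: int
    d_prime: float
    ci_low: float
    ci_high: float
    cls: str


@dataclass(frozen=True)
class LinkageBlockDef:
    """A linkage block: contiguous member SNPs and their genomic interval.

    ``start_bp``/``end_bp`` are the 1-based positions of the first and last
    member SNP; ``length_bp`` is their difference (not +1), the convention
    used throughout block summary tables.
    """

    block_id: str
    chrom: str
    start_bp: int
    end_bp: int
    snp_indices: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.end_bp < self.start_bp:
            raise ValueError(f"{self.block_id}: end_bp < start_bp")
        if self.snp_indices and len(self.snp_indices) < 2:
            raise ValueError(f"{self.block_id}: a block needs >= 2 SNPs")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp

    @property
    def n_snps(self) -> int:
        return len(self.snp_indices)


def pair_dprime_ci(
    counts: Sequence[int],
    grid_step: float = 0.001,
    ci_mass: float = 0.90,
) -> tuple[float, float, float]:
    """D' and its likelihood-based confidence bounds for one SNP pair.

    Parameters
    ----------
    counts
        Haplotype counts ``(n_AB, n_Ab, n_aB, n_ab)`` observed directly on
        phased chromosomes.
    grid_step
        Resolution of the ``|D'|`` grid on [0, 1].
    ci_mass
        Central mass of the normalized likelihood enclosed by the bounds
        (0.90 gives the conventional 5th/95th percentile bounds).

    Returns
    -------
    (d_prime, ci_low, ci_high)

    Notes
    -----
    Allele frequencies are fixed at their sample values; the multinomial
    likelihood of the observed haplotype counts is evaluated at every grid
    value of ``|D'|`` (with the sign of the observed D), normalized, and
    the bounds are the grid points where the cumulative normalized
    likelihood crosses ``(1-ci_mass)/2`` and ``1-(1-ci_mass)/2``.
    """
    n_ab_, n_aB_, n_Ab_, n_AB_ = counts[3], counts[2], counts[1], counts[0]
    arr = np.asarray([n_AB_, n_Ab_, n_aB_, n_ab_], dtype=float)
    n = arr.sum()
    if n <= 0:
        raise ValueError("empty haplotype count table")
    p_a = (arr[0] + arr[1]) / n  # freq of allele A at first SNP
    p_b = (arr[0] + arr[2]) / n  # freq of allele B at second SNP
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise MonomorphicPairError("monomorphic SNP in pair")

    d_obs = arr[0] / n - p_a * p_b
    if d_obs >= 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
        sign = 1.0
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
        sign = -1.0
    d_prime = abs(d_obs) / d_max if d_max > 0 else 0.0
    d_prime = min(d_prime, 1.0)

    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    d_vals = sign * grid * d_max
    freqs = np.empty((grid.size, 4))
    freqs[:, 0] = p_a * p_b + d_vals
    freqs[:, 1] = p_a * (1 - p_b) - d_vals
    freqs[:, 2] = (1 - p_a) * p_b - d_vals
    freqs[:, 3] = (1 - p_a) * (1 - p_b) + d_vals
    np.clip(freqs, 0.0, 1.0, out=freqs)

    with np.errstate(divide="ignore", invalid="ignore"):
        logf = np.where(freqs > 0, np.log(freqs), -np.inf)
        terms = np.where(arr > 0, logf * arr, 0.0)
    loglik = terms.sum(axis=1)
    loglik -= loglik.max()
    lik = np.exp(loglik)
    lik /= lik.sum()
    cum = np.cumsum(lik)

    lo_mass = (1.0 - ci_mass) / 2.0
    hi_mass = 1.0 - lo_mass
    ci_low = float(grid[np.searchsorted(cum, lo_mass)])
    ci_high = float(grid[min(np.searchsorted(cum, hi_mass), grid.size - 1)])
    return float(d_prime), ci_low, ci_high


def classify_pair(
    ci_low: float,
    ci_high: float,
    strong_high: float = 0.98,
    strong_low: float = 0.70,
    recomb_high: float = 0.90,
) -> str:
    """Classify a pair from its ``|D'|`` confidence bounds.

    Strong LD requires the upper bound to reach ``strong_high`` and the
    lower bound ``strong_low``; strong recombination is an upper bound
    below ``recomb_high``; everything else is uninformative.
    """
    if ci_high >= strong_high and ci_low >= strong_low:
        return STRONG_LD
    if ci_high < recomb_high:
        return STRONG_RECOMB
    return UNINFORMATIVE


def compute_pair_classes(
    haplotypes: np.ndarray,
    snps: Sequence[SnpRecord],
    max_span_kb: float = 400.0,
    grid_step: float = 0.001,
    ci_mass: float = 0.90,
    thresholds: tuple[float, float, float] = (0.98, 0.70, 0.90),
) -> dict[tuple[int, int], PairClass]:
    """Classify all SNP pairs within ``max_span_kb`` on the same chromosome.

    ``haplotypes`` is a (2N, S) 0/1 matrix of phased chromosomes.
    """
    max_span = max_span_kb * 1000
    out: dict[tuple[int, int], PairClass] = {}
    n_snps = len(snps)
    for i in range(n_snps):
        col_i = haplotypes[:, i]
        for j in range(i + 1, n_snps):
            if snps[j].chrom != snps[i].chrom:
                break
            if snps[j].pos - snps[i].pos > max_span:
                break
            col_j = haplotypes[:, j]
            n11 = int(np.sum((col_i == 0) & (col_j == 0)))
            n10 = int(np.sum((col_i == 0) & (col_j == 1)))
            n01 = int(np.sum((col_i == 1) & (col_j == 0)))
            n00 = int(np.sum((col_i == 1) & (col_j == 1)))
            try:
                dp, lo, hi = pair_dprime_ci((n11, n10, n01, n00), grid_step, ci_mass)
            except MonomorphicPairError:
                out[(i, j)] = PairClass(i, j, float("nan"), float("nan"),
                                        float("nan"), UNINFORMATIVE)
                continue
            cls = classify_pair(lo, hi, *thresholds)
            out[(i, j)] = PairClass(i, j, dp, lo, hi, cls)
    return out


def find_blocks(
    pair_classes: Mapping[tuple[int, int], PairClass],
    snps: Sequence[SnpRecord],
    max_span_kb: float = 400.0,
    informative_fraction: float = 0.95,
) -> list[LinkageBlockDef]:
    """Assemble blocks from pairwise LD classifications.

    A candidate block is an index range whose outermost pair is strong LD
    and whose physical span does not exceed ``max_span_kb``; it is accepted
    when, among the informative pairs it contains, the fraction of strong-LD
    pairs is at least ``informative_fraction``.  Candidates are processed
    longest-span first (ties to the leftmost start) and later candidates
    overlapping an accepted block are discarded.  Accepted blocks are then
    labelled ``LB1, LB2, ...`` in genomic order.
    """
    max_span = max_span_kb * 1000
    candidates = []
    for (i, j), pc in pair_classes.items():
        if pc.cls != STRONG_LD:
            continue
        if snps[i].chrom != snps[j].chrom:
            continue
        span = snps[j].pos - snps[i].pos
        if span > max_span:
            continue
        n_strong = n_recomb = 0
        for a in range(i, j + 1):
            for b in range(a + 1, j + 1):
                pc_ab = pair_classes.get((a, b))
                if pc_ab is None:
                    continue
                if pc_ab.cls == STRONG_LD:
                    n_strong += 1
                elif pc_ab.cls == STRONG_RECOMB:
                    n_recomb += 1
        informative = n_strong + n_recomb
        if informative == 0 or n_strong / informative < informative_fraction:
            continue
        candidates.append((span, i, j))

    candidates.sort(key=lambda c: (-c[0], snps[c[1]].pos, c[1]))
    taken: list[tuple[int, int]] = []
    accepted = []
    for span, i, j in candidates:
        if any(i <= b and a <= j for a, b in taken):
            continue
        taken.append((i, j))
        accepted.append((i, j))

    accepted.sort(key=lambda ij: (snps[ij[0]].chrom, snps[ij[0]].pos))
    blocks = []
    for k, (i, j) in enumerate(accepted, start=1):
        blocks.append(
            LinkageBlockDef(
                block_id=f"LB{k}",
                chrom=snps[i].chrom,
                start_bp=snps[i].pos,
                end_bp=snps[j].pos,
                snp_indices=tuple(range(i, j + 1)),
            )
        )
    return blocks


def detect_blocks(
    haplotypes: np.ndarray,
    snps: Sequence[SnpRecord],
    max_span_kb: float = 400.0,
    informative_fraction: float = 0.95,
    grid_step: float = 0.001,
    ci_mass: float = 0.90,
    thresholds: tuple[float, float, float] = (0.98, 0.70, 0.90),
) -> list[LinkageBlockDef]:
    """End-to-end block detection on a phased 0/1 haplotype matrix."""
    classes = compute_pair_classes(
        haplotypes, snps, max_span_kb, grid_step, ci_mass, thresholds
    )
    return find_blocks(classes, snps, max_span_kb, informative_fraction)


# ---------------------------------------------------------------------------
# PLINK .blocks.det interoperability
# ---------------------------------------------------------------------------

def read_plink_blocks(
    path: str | Path, snps: Sequence[SnpRecord]
) -> list[LinkageBlockDef]:
    """Read precomputed blocks in PLINK ``.blocks.det`` format.

    Columns: ``CHR BP1 BP2 KB NSNPS SNPS`` with SNPS a ``|``-separated list
    of member SNP names.  Blocks naming a SNP absent from ``snps`` are
    skipped with a warning; malformed rows are fatal.
    """
    by_name = {s.id: k for k, s in enumerate(snps)}
    blocks: list[LinkageBlockDef] = []
    with open(path) as fh:
        header = fh.readline().split()
        if header[:6] != ["CHR", "BP1", "BP2", "KB", "NSNPS", "SNPS"]:
            raise ValueError(f"{path}: not a .blocks.det header: {header}")
        for ln, line in enumerate(fh, start=2):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 6:
                raise ValueError(f"{path}:{ln}: malformed row: {line!r}")
            chrom, bp1, bp2 = fields[0], int(fields[1]), int(fields[2])
            names = fields[5].split("|")
            try:
                idx = tuple(sorted(by_name[nm] for nm in names))
            except KeyError as exc:
                warnings.warn(
                    f"{path}:{ln}: unknown SNP {exc.args[0]!r}; block skipped"
                )
                continue
            blocks.append(
                LinkageBlockDef(
                    block_id=f"LB{len(blocks) + 1}",
                    chrom=chrom,
                    start_bp=bp1,
                    end_bp=bp2,
                    snp_indices=idx,
                )
            )
    return blocks


def write_plink_blocks(
    blocks: Sequence[LinkageBlockDef],
    snps: Sequence[SnpRecord],
    path: str | Path,
) -> None:
    """Write blocks in the PLINK ``.blocks.det`` dialect."""
    with open(path, "w") as fh:
        fh.write("CHR BP1 BP2 KB NSNPS SNPS\n")
        for blk in blocks:
            names = "|".join(snps[k].id for k in blk.snp_indices)
            fh.write(
                f"{blk.chrom} {blk.start_bp} {blk.end_bp} "
                f"{blk.length_bp / 1000:.3f} {blk.n_snps} {names}\n"
            )


def write_block_bed(blocks: Sequence[LinkageBlockDef], path: str | Path) -> None:
    """Write blocks as BED (0-based half-open, name = block id)."""
    with open(path, "w") as fh:
        for blk in blocks:
            fh.write(f"{blk.chrom}\t{blk.start_bp - 1}\t{blk.end_bp}\t{blk.block_id}\n")


def blocks_to_frame(blocks: Sequence[LinkageBlockDef]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "block_id": b.block_id,
                "chrom": b.chrom,
                "start_bp": b.start_bp,
                "end_bp": b.end_bp,
                "length_bp": b.length_bp,
                "n_snps": b.n_snps,
            }
            for b in blocks
        ]
    )
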
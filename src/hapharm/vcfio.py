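"""Phased VCF reading and writing.

Haplotypes are exchanged as VCF v4.2 with phased GT fields (``0|1``).
Reading goes through :mod:`cyvcf2`; writing emits minimal, sorted,
spec-conformant text.  The in-memory representation is a (2N, S) 0/1
matrix with rows ``2i`` (paternal) and ``2i+1`` (maternal) per sample.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np

from .blocks import SnpRecord

__all__ = ["write_phased_vcf", "read_phased_vcf"]

# arbitrary but fixed REF/ALT symbols for the binary alleles
_REF, _ALT = "A", "G"


def write_phased_vcf(
    path: str | Path,
    snps: Sequence[SnpRecord],
    haplotypes: np.ndarray,
    samples: Sequence[str],
) -> None:
    """Write a phased VCF; variants must already be position-sorted."""
    if haplotypes.shape != (2 * len(samples), len(snps)):
        raise ValueError("haplotype matrix shape does not match samples/snps")
    chroms = []
    for s in snps:
        if s.chrom not in chroms:
            chroms.append(s.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=hapharm\n")
        for chrom in chroms:
            length = max(s.pos for s in snps if s.chrom == chrom) + 1
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for k, snp in enumerate(snps):
            col = haplotypes[:, k]
            gts = "\t".join(
                f"{col[2 * i]}|{col[2 * i + 1]}" for i in range(len(samples))
            )
            fh.write(
                f"{snp.chrom}\t{snp.pos}\t{snp.id}\t{_REF}\t{_ALT}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_phased_vcf(
    path: str | Path,
) -> tuple[list[SnpRecord], np.ndarray, list[str]]:
    """Read a phased VCF into (snps, (2N, S) 0/1 matrix, sample ids).

    Unphased or missing genotypes are fatal: downstream haplotype coding
    requires complete phased data.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snps: list[SnpRecord] = []
    cols: list[np.ndarray] = []
    for var in vcf:
        gts = np.asarray(var.genotypes)  # (N, 3): a, b, phased
        if np.any(gts[:, 0] < 0) or np.any(gts[:, 1] < 0):
            raise ValueError(f"{var.ID}: missing genotype; impute first")
        if not np.all(gts[:, 2]):
            raise ValueError(f"{var.ID}: unphased genotype")
        snps.append(
            SnpRecord(
                chrom=var.CHROM,
                pos=var.POS,
                id=var.ID or f"{var.CHROM}:{var.POS}",
                ref=var.REF,
                alt=var.ALT[0] if var.ALT else ".",
            )
        )
        cols.append(gts[:, :2].reshape(-1))
    vcf.close()
    matrix = (
        np.stack(cols, axis=1).astype(np.uint8)
        if cols
        else np.empty((2 * len(samples), 0), dtype=np.uint8)
    )
    return snps, matrix, samples
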
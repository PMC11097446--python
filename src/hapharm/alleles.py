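"""Coding of within-block haplotypes as multi-allelic marker alleles.

Each linkage block is treated as one codominant (microsatellite-like)
locus.  Every distinct SNP-allele string observed within a block becomes
an allele with a 3-digit code, assigned consecutively from 101 in order of
first observation (individuals in input order, paternal haplotype before
maternal).  The coding is a per-block bijection between haplotype strings
and codes; permuting individuals can relabel alleles but never changes
which haplotypes are grouped together.

Codes at or above :data:`NOVEL_CODE_BASE` (900) are reserved for synthetic
error alleles injected by the simulator and are never produced by the
coder, which makes planted errors recognizable in tests.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .blocks import LinkageBlockDef

__all__ = [
    "FIRST_CODE",
    "NOVEL_CODE_BASE",
    "MAX_CODE",
    "code_block_haplotypes",
    "compute_allele_stats",
    "compute_scope_stats",
    "observed_homozygosity",
    "cohort_private_alleles",
]

FIRST_CODE = 101
NOVEL_CODE_BASE = 900
MAX_CODE = 999

SCOPES = ("BP", "G12", "G23", "G3", "WP")


def code_block_haplotypes(
    haplotypes: np.ndarray,
    blocks: Sequence[LinkageBlockDef],
    individuals: Sequence[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign 3-digit allele codes per block and genotype every individual.

    Parameters
    ----------
    haplotypes
        (2N, S) phased 0/1 matrix; rows ``2i`` and ``2i+1`` are the
        paternal and maternal haplotype of ``individuals[i]``.  Negative
        entries (missing calls) are fatal: inputs must be imputed first.
    blocks
        Block definitions whose ``snp_indices`` index columns of the matrix.
    individuals
        Individual identifiers in matrix row order.

    Returns
    -------
    registry, genotypes
        ``registry`` has columns ``block_id, code, haplotype`` (haplotype
        as a string of 0/1 characters); ``genotypes`` has one row per
        (individual, block) with columns
        ``individual, block_id, allele1, allele2`` where allele1 is the
        paternal slot.
    """
    if haplotypes.shape[0] != 2 * len(individuals):
        raise ValueError("haplotype matrix must have two rows per individual")
    if np.any(haplotypes < 0):
        raise ValueError("missing genotypes present; impute before coding")

    reg_rows = []
    geno_rows = []
    for blk in blocks:
        sub = np.ascontiguousarray(haplotypes[:, list(blk.snp_indices)], dtype=np.uint8)
        codes: dict[bytes, int] = {}
        row_codes = np.empty(sub.shape[0], dtype=np.int16)
        for r in range(sub.shape[0]):
            key = sub[r].tobytes()
            code = codes.get(key)
            if code is None:
                code = FIRST_CODE + len(codes)
                if code >= NOVEL_CODE_BASE:
                    raise ValueError(
                        f"{blk.block_id}: more than "
                        f"{NOVEL_CODE_BASE - FIRST_CODE} distinct haplotypes"
                    )
                codes[key] = code
                reg_rows.append(
                    {
                        "block_id": blk.block_id,
                        "code": code,
                        "haplotype": "".join(map(str, sub[r])),
                    }
                )
            row_codes[r] = code
        for k, ind in enumerate(individuals):
            geno_rows.append(
                {
                    "individual": ind,
                    "block_id": blk.block_id,
                    "allele1": int(row_codes[2 * k]),
                    "allele2": int(row_codes[2 * k + 1]),
                }
            )
    registry = pd.DataFrame(reg_rows, columns=["block_id", "code", "haplotype"])
    genotypes = pd.DataFrame(
        geno_rows, columns=["individual", "block_id", "allele1", "allele2"]
    )
    return registry, genotypes


def compute_allele_stats(
    genotypes: pd.DataFrame,
    scope_ids: Sequence[str],
    scope: str,
) -> pd.DataFrame:
    """Per-allele statistics within one scope.

    For every (block, code) carried by at least one individual of the
    scope: copy count, frequency ``q = copies / 2N`` with ``N`` the number
    of scope individuals, minor-allele frequency and observed homozygote
    count.  Alleles absent from the scope are omitted.
    """
    ids = set(scope_ids)
    if not ids:
        raise ValueError(f"scope {scope!r} is empty")
    sub = genotypes[genotypes["individual"].isin(ids)]
    n = sub["individual"].nunique()
    if n == 0:
        raise ValueError(f"scope {scope!r} has no genotyped individuals")

    long = pd.concat(
        [
            sub[["block_id", "allele1"]].rename(columns={"allele1": "code"}),
            sub[["block_id", "allele2"]].rename(columns={"allele2": "code"}),
        ]
    )
    copies = long.groupby(["block_id", "code"]).size().rename("copies")
    hom = (
        sub[sub["allele1"] == sub["allele2"]]
        .groupby(["block_id", "allele1"])
        .size()
        .rename("hom_count")
    )
    hom.index = hom.index.set_names(["block_id", "code"])
    stats = pd.concat([copies, hom], axis=1).fillna({"hom_count": 0}).reset_index()
    stats["hom_count"] = stats["hom_count"].astype(int)
    stats["scope"] = scope
    stats["N"] = n
    stats["q"] = stats["copies"] / (2 * n)
    stats["maf"] = np.minimum(stats["q"], 1 - stats["q"])
    return stats[
        ["block_id", "code", "scope", "copies", "q", "maf", "hom_count", "N"]
    ]


def compute_scope_stats(
    genotypes: pd.DataFrame, cohorts: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Allele statistics for each cohort and the whole population (WP)."""
    out = {}
    for scope in ("BP", "G12", "G23", "G3"):
        ids = cohorts.loc[cohorts["cohort"] == scope, "id"]
        if len(ids):
            out[scope] = compute_allele_stats(genotypes, ids, scope)
    out["WP"] = compute_allele_stats(genotypes, cohorts["id"], "WP")
    return out


def observed_homozygosity(
    genotypes: pd.DataFrame, scope_ids: Sequence[str] | None = None
) -> float:
    """Fraction of (individual, block) genotypes homozygous in scope."""
    sub = genotypes
    if scope_ids is not None:
        sub = genotypes[genotypes["individual"].isin(set(scope_ids))]
    if len(sub) == 0:
        raise ValueError("no genotypes in scope")
    return float((sub["allele1"] == sub["allele2"]).mean())


def cohort_private_alleles(stats: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Alleles carried in exactly one cohort.

    ``stats`` maps cohort label to its allele-statistics frame (as from
    :func:`compute_scope_stats`; a WP entry, if present, is ignored).
    Returns columns ``block_id, code, cohort``.
    """
    frames = []
    for cohort, df in stats.items():
        if cohort == "WP":
            continue
        frames.append(df.loc[df["copies"] > 0, ["block_id", "code"]].assign(cohort=cohort))
    allc = pd.concat(frames, ignore_index=True)
    counts = allc.groupby(["block_id", "code"])["cohort"].nunique()
    private = counts[counts == 1].index
    out = allc.set_index(["block_id", "code"]).loc[private].reset_index()
    return out.sort_values(["cohort", "block_id", "code"]).reset_index(drop=True)
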
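"""Parent–offspring consistency auditing at multi-allelic block loci.

A trio genotype (offspring, father, mother) at one block locus is
Mendelian-consistent when some assignment sends one offspring allele to
the father's pair and the other to the mother's pair.  Inconsistencies are
attributed deterministically:

* an offspring allele present in neither parent is a mismatch attributed
  to the **offspring** (one per such slot) — the Allele-Drop-In signature;
* when every offspring allele occurs in some parent but no joint
  assignment works (both offspring alleles are only matchable to the same
  parent), one mismatch is attributed to the parent that transmits
  nothing (**father** or **mother**).

Error rates follow the microsatellite parentage-testing convention:
``e_l = m_l / nt`` (mean rate per locus) and ``e_a = m_a / (2 nt)``
(mean rate per allele), where ``m_l`` counts single-locus genotypes with
at least one allelic mismatch, ``m_a`` counts allelic mismatches, and
``nt`` is the number of replicated single-locus genotypes — here the
number of offspring with both parents genotyped times the number of loci.
The fraction of loci carrying at least one inconsistency is reported
separately as ``lb_fraction``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pedigree import Family, Pedigree

__all__ = [
    "TrioMismatch",
    "ErrorRates",
    "trio_check",
    "audit_population",
    "family_size_summary",
]

Genotype = tuple[int, int]


@dataclass(frozen=True)
class TrioMismatch:
    """One inconsistent trio genotype at one block locus."""

    offspring: str
    block_id: str
    n_mismatch_slots: int
    codes: tuple[int, ...]
    attribution: str  # offspring | father | mother

    def __post_init__(self) -> None:
        if self.n_mismatch_slots not in (1, 2):
            raise ValueError("n_mismatch_slots must be 1 or 2")
        if self.attribution not in ("offspring", "father", "mother"):
            raise ValueError(f"bad attribution {self.attribution!r}")


@dataclass(frozen=True)
class ErrorRates:
    """Mismatch tallies and the derived per-locus / per-allele rates."""

    m_a: int  # total allelic mismatches
    m_l: int  # single-locus genotypes with >= 1 mismatch
    nt: int  # replicated single-locus genotypes (eligible offspring x loci)
    n_loci_with_mismatch: int = 0
    n_loci: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.m_l <= self.m_a <= 2 * self.nt):
            raise ValueError("require 0 <= m_l <= m_a <= 2*nt")

    @property
    def e_a(self) -> float:
        """Mean error rate per allele, ``m_a / (2 nt)``."""
        return self.m_a / (2 * self.nt) if self.nt else 0.0

    @property
    def e_l(self) -> float:
        """Mean error rate per locus, ``m_l / nt``."""
        return self.m_l / self.nt if self.nt else 0.0

    @property
    def lb_fraction(self) -> float:
        """Fraction of loci carrying at least one inconsistency."""
        return self.n_loci_with_mismatch / self.n_loci if self.n_loci else 0.0


def trio_check(
    offspring_gt: Genotype,
    father_gt: Genotype,
    mother_gt: Genotype,
    offspring: str = "",
    block_id: str = "",
) -> list[TrioMismatch]:
    """Check one trio at one locus; return mismatches (empty if consistent)."""
    o = tuple(offspring_gt)
    f = set(father_gt)
    m = set(mother_gt)
    x, y = o
    if (x in f and y in m) or (y in f and x in m):
        return []
    missing = [a for a in o if a not in f and a not in m]
    if missing:
        return [
            TrioMismatch(
                offspring=offspring,
                block_id=block_id,
                n_mismatch_slots=len(missing),
                codes=tuple(missing),
                attribution="offspring",
            )
        ]
    # every offspring allele exists in a parent, but both can only come
    # from the same one: blame the parent that transmits nothing
    attribution = "mother" if set(o) <= f else "father"
    culprit_parent = m if attribution == "mother" else f
    offending = tuple(sorted(set(o) - culprit_parent))
    return [
        TrioMismatch(
            offspring=offspring,
            block_id=block_id,
            n_mismatch_slots=1,
            codes=offending,
            attribution=attribution,
        )
    ]


def _genotype_arrays(
    genotypes: pd.DataFrame,
) -> tuple[dict[str, int], list[str], np.ndarray]:
    """Pivot the long genotype table to (individual x block x 2) codes."""
    inds = genotypes["individual"].unique().tolist()
    blocks = genotypes["block_id"].unique().tolist()
    ind_ix = {v: k for k, v in enumerate(inds)}
    blk_ix = {v: k for k, v in enumerate(blocks)}
    arr = np.full((len(inds), len(blocks), 2), -1, dtype=np.int32)
    ii = genotypes["individual"].map(ind_ix).to_numpy()
    bb = genotypes["block_id"].map(blk_ix).to_numpy()
    arr[ii, bb, 0] = genotypes["allele1"].to_numpy()
    arr[ii, bb, 1] = genotypes["allele2"].to_numpy()
    return ind_ix, blocks, arr


def audit_population(
    genotypes: pd.DataFrame,
    ped: Pedigree,
    cohorts: pd.DataFrame | None = None,
    families: Sequence[Family] | None = None,
) -> tuple[pd.DataFrame, ErrorRates, dict]:
    """Run :func:`trio_check` over every eligible offspring and every block.

    An offspring is eligible when both its parents are genotyped;
    individuals lacking a genotyped parent contribute no trios (base
    population members are audited only as parents).

    Returns the mismatch table (columns ``offspring, block_id, slots,
    codes, attribution``), the population :class:`ErrorRates`, and a tally
    dict with per-attribution, per-cohort and per-family counts.
    """
    ind_ix, block_ids, arr = _genotype_arrays(genotypes)
    eligible = [
        ind
        for ind in ind_ix
        if ind in ped
        and all(p is not None and p in ind_ix for p in ped.parents(ind))
    ]
    mismatches: list[TrioMismatch] = []
    for ind in eligible:
        sire, dam = ped.parents(ind)
        o_row = arr[ind_ix[ind]]
        f_row = arr[ind_ix[sire]]
        m_row = arr[ind_ix[dam]]
        for b, block_id in enumerate(block_ids):
            o = o_row[b]
            if o[0] < 0:
                continue  # locus not genotyped for this offspring
            mismatches.extend(
                trio_check(
                    (int(o[0]), int(o[1])),
                    (int(f_row[b, 0]), int(f_row[b, 1])),
                    (int(m_row[b, 0]), int(m_row[b, 1])),
                    offspring=ind,
                    block_id=block_id,
                )
            )

    mm = pd.DataFrame(
        [
            {
                "offspring": t.offspring,
                "block_id": t.block_id,
                "slots": t.n_mismatch_slots,
                "codes": ",".join(map(str, t.codes)),
                "attribution": t.attribution,
            }
            for t in mismatches
        ],
        columns=["offspring", "block_id", "slots", "codes", "attribution"],
    )
    n_loci = len(block_ids)
    nt = len(eligible) * n_loci
    rates = ErrorRates(
        m_a=int(mm["slots"].sum()) if len(mm) else 0,
        m_l=int(len(mm)),
        nt=nt,
        n_loci_with_mismatch=int(mm["block_id"].nunique()) if len(mm) else 0,
        n_loci=n_loci,
    )

    tallies: dict = {
        "by_attribution": mm.groupby("attribution")["slots"].sum().to_dict()
        if len(mm)
        else {},
        "n_eligible_offspring": len(eligible),
    }
    if cohorts is not None and len(mm):
        coh = cohorts.set_index("id")["cohort"]
        tallies["by_cohort"] = (
            mm.assign(cohort=mm["offspring"].map(coh))
            .groupby("cohort")["slots"]
            .sum()
            .to_dict()
        )
    if families is not None:
        tallies["by_family"] = {}
        off2fam = {
            o: k for k, fam in enumerate(families) for o in fam.offspring
        }
        if len(mm):
            fam_series = mm["offspring"].map(off2fam)
            sums = mm.assign(fam=fam_series).groupby("fam")["slots"].sum()
        else:
            sums = pd.Series(dtype=int)
        for k, fam in enumerate(families):
            tallies["by_family"][(fam.sire, fam.dam)] = int(sums.get(k, 0))
    return mm, rates, tallies


def family_size_summary(
    mismatches: pd.DataFrame, families: Sequence[Family]
) -> pd.DataFrame:
    """Total and mean mismatch count per family.

    Columns: ``sire, dam, size, total_mismatches, mean_per_offspring``.
    Family totals over all families whose offspring are audited sum to the
    population ``m_a``.
    """
    per_off = (
        mismatches.groupby("offspring")["slots"].sum()
        if len(mismatches)
        else pd.Series(dtype=int)
    )
    rows = []
    for fam in families:
        total = int(sum(per_off.get(o, 0) for o in fam.offspring))
        rows.append(
            {
                "sire": fam.sire,
                "dam": fam.dam,
                "size": fam.size,
                "total_mismatches": total,
                "mean_per_offspring": total / fam.size if fam.size else 0.0,
            }
        )
    return pd.DataFrame(
        rows, columns=["sire", "dam", "size", "total_mismatches", "mean_per_offspring"]
    )
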
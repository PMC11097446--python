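"""Ancestor-based segregation classification of candidate alleles.

A genotype-calling artifact can plant an allele in a single individual
(or, when driven by an inherited feature such as a CNV, in a parent and a
subset of its descendants), whereas a real allele segregating from the
founders leaves a verifiable transmission trail.  For each candidate
allele we therefore record whether the allele can be found in the fathers,
mothers, paternal grandparents and maternal grandparents of its carriers
(unions over all carriers; untyped ancestors contribute nothing) and
classify:

* ``de_novo`` — in no ancestor of any carrier: the Allele-Drop-In profile;
* ``parent_only`` — in a parent but no grandparent;
* ``grandparent_only`` — in a grandparent but no parent, a transmission
  gap that real inheritance cannot produce;
* ``segregant`` — in fathers, mothers and both grandparental classes:
  a two-generation transmission trail, the only class trusted as a real
  potentially harmful allele;
* ``parent_and_grandparent`` — any remaining mixed pattern.

Grandparent flags deliberately do not require the connecting parent to
carry the allele: the gap patterns are exactly the artifact signature the
classification is designed to expose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pedigree import Pedigree

__all__ = [
    "AncestorPresence",
    "SEGREGATION_CLASSES",
    "GenotypeLookup",
    "ancestor_presence",
    "classify_allele_segregation",
    "trace_alleles",
    "venn_table",
    "carrier_pedigree_dot",
]

SEGREGATION_CLASSES = (
    "de_novo",
    "parent_only",
    "grandparent_only",
    "parent_and_grandparent",
    "segregant",
)


@dataclass(frozen=True)
class AncestorPresence:
    """Presence of one allele in the four ancestor classes of its carriers."""

    block_id: str
    code: int
    in_father: bool
    in_mother: bool
    in_pgp: bool  # any paternal grandparent of any carrier
    in_mgp: bool  # any maternal grandparent of any carrier
    carrier_count: int
    copies: int


class GenotypeLookup:
    """Fast carrier queries over a long block-genotype table."""

    def __init__(self, genotypes: pd.DataFrame):
        self._pairs: dict[tuple[str, str], tuple[int, int]] = {}
        self._carriers: dict[tuple[str, int], list[str]] = {}
        for row in genotypes.itertuples(index=False):
            a1, a2 = int(row.allele1), int(row.allele2)
            self._pairs[(row.individual, row.block_id)] = (a1, a2)
            self._carriers.setdefault((row.block_id, a1), []).append(row.individual)
            if a2 != a1:
                self._carriers.setdefault((row.block_id, a2), []).append(row.individual)

    def has_allele(self, individual: str | None, block_id: str, code: int) -> bool:
        if individual is None:
            return False
        pair = self._pairs.get((individual, block_id))
        return pair is not None and code in pair

    def copies_of(self, individual: str, block_id: str, code: int) -> int:
        pair = self._pairs.get((individual, block_id))
        if pair is None:
            return 0
        return (pair[0] == code) + (pair[1] == code)

    def carriers(self, block_id: str, code: int) -> list[str]:
        return self._carriers.get((block_id, code), [])


def ancestor_presence(
    block_id: str,
    code: int,
    genotypes: GenotypeLookup,
    ped: Pedigree,
) -> AncestorPresence:
    """OR the allele's presence in each ancestor class over all carriers."""
    carriers = genotypes.carriers(block_id, code)
    in_father = in_mother = in_pgp = in_mgp = False
    copies = 0
    for carrier in carriers:
        copies += genotypes.copies_of(carrier, block_id, code)
        if carrier not in ped:
            continue
        sire, dam = ped.parents(carrier)
        if genotypes.has_allele(sire, block_id, code):
            in_father = True
        if genotypes.has_allele(dam, block_id, code):
            in_mother = True
        if sire is not None and sire in ped:
            for gp in ped.parents(sire):
                if genotypes.has_allele(gp, block_id, code):
                    in_pgp = True
        if dam is not None and dam in ped:
            for gp in ped.parents(dam):
                if genotypes.has_allele(gp, block_id, code):
                    in_mgp = True
    return AncestorPresence(
        block_id=block_id,
        code=code,
        in_father=in_father,
        in_mother=in_mother,
        in_pgp=in_pgp,
        in_mgp=in_mgp,
        carrier_count=len(carriers),
        copies=copies,
    )


def classify_allele_segregation(presence: AncestorPresence) -> str:
    """Map an :class:`AncestorPresence` to its segregation class."""
    in_parent = presence.in_father or presence.in_mother
    in_gp = presence.in_pgp or presence.in_mgp
    if not in_parent and not in_gp:
        return "de_novo"
    if (
        presence.in_father
        and presence.in_mother
        and presence.in_pgp
        and presence.in_mgp
    ):
        return "segregant"
    if in_parent and not in_gp:
        return "parent_only"
    if in_gp and not in_parent:
        return "grandparent_only"
    return "parent_and_grandparent"


def trace_alleles(
    alleles: pd.DataFrame,
    genotypes: pd.DataFrame | GenotypeLookup,
    ped: Pedigree,
) -> pd.DataFrame:
    """Presence flags and segregation class for every (block, code) row.

    ``alleles`` needs columns ``block_id, code`` (e.g. a candidate-call
    frame filtered to ``is_candidate``).
    """
    lookup = (
        genotypes
        if isinstance(genotypes, GenotypeLookup)
        else GenotypeLookup(genotypes)
    )
    rows = []
    for row in alleles[["block_id", "code"]].drop_duplicates().itertuples(index=False):
        pres = ancestor_presence(row.block_id, int(row.code), lookup, ped)
        rows.append(
            {
                "block_id": pres.block_id,
                "code": pres.code,
                "in_father": pres.in_father,
                "in_mother": pres.in_mother,
                "in_pgp": pres.in_pgp,
                "in_mgp": pres.in_mgp,
                "carrier_count": pres.carrier_count,
                "copies": pres.copies,
                "segregation_class": classify_allele_segregation(pres),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "block_id",
            "code",
            "in_father",
            "in_mother",
            "in_pgp",
            "in_mgp",
            "carrier_count",
            "copies",
            "segregation_class",
        ],
    )


_FLAGS = ("in_father", "in_mother", "in_pgp", "in_mgp")
_FLAG_LABELS = ("F", "M", "PGP", "MGP")


def venn_table(presences: pd.DataFrame) -> dict[str, int]:
    """Counts of alleles per combination of the four ancestor flags.

    Keys are '+'-joined flag labels (``F``, ``M``, ``PGP``, ``MGP``) plus
    ``none``; values sum to the number of alleles.
    """
    cells: dict[str, int] = {"none": 0}
    for mask in range(1, 16):
        key = "+".join(l for k, l in enumerate(_FLAG_LABELS) if mask >> k & 1)
        cells[key] = 0
    for row in presences.itertuples(index=False):
        mask = sum(
            1 << k for k, flag in enumerate(_FLAGS) if bool(getattr(row, flag))
        )
        if mask == 0:
            cells["none"] += 1
        else:
            key = "+".join(l for k, l in enumerate(_FLAG_LABELS) if mask >> k & 1)
            cells[key] += 1
    return cells


def carrier_pedigree_dot(
    block_id: str,
    code: int,
    genotypes: GenotypeLookup,
    ped: Pedigree,
) -> str:
    """DOT export of the sub-pedigree spanned by an allele's carriers."""
    carriers = set(genotypes.carriers(block_id, code))
    nodes = set(carriers)
    for c in list(carriers):
        if c not in ped:
            continue
        for p in ped.parents(c):
            if p is not None:
                nodes.add(p)
                for gp in ped.parents(p) if p in ped else ():
                    if gp is not None:
                        nodes.add(gp)
    lines = [f'digraph "{block_id}_{code}" {{']
    for n in sorted(nodes):
        sex = ped.record(n).sex if n in ped else "unknown"
        shape = {"male": "box", "female": "ellipse"}.get(sex, "diamond")
        fill = ", style=filled, fillcolor=gray" if n in carriers else ""
        lines.append(f'  "{n}" [shape={shape}{fill}];')
    for n in sorted(nodes):
        if n not in ped:
            continue
        for p in ped.parents(n):
            if p in nodes:
                lines.append(f'  "{p}" -> "{n}";')
    lines.append("}")
    return "\n".join(lines)
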
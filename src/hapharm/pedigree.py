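"""Pedigree ingestion, pedigree depth and cohort assignment.

A pedigree is a collection of individuals with optional sire/dam links.
Pedigree depth is measured in *equivalents to complete generations* (``t``),
the sum over all known ancestors of ``(1/2)**n`` where ``n`` is the number
of generations separating the ancestor from the individual.  ``t`` is the
standard measure of pedigree completeness in livestock genetics: a founder
has ``t = 0``, an individual with two founder parents has ``t = 1``, and a
pedigree that is complete for ``g`` generations gives exactly ``t = g``.

Cohorts stratify the population by pedigree depth: an explicit base
population (BP) list, then ``G12`` (``t <= 2``), ``G23`` (``2 < t <= 3``)
and ``G3`` (``t > 3``).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "UNKNOWN",
    "PedigreeRecord",
    "Pedigree",
    "PedigreeError",
    "Family",
    "load_pedigree",
    "equivalent_complete_generations",
    "assign_cohorts",
    "enumerate_families",
    "write_cohort_table",
]

#: Sentinel for an unknown parent.  In files, an empty field or "0".
UNKNOWN = None

_UNKNOWN_TOKENS = {"", "0", "NA", "na", "NaN", "nan"}

_SEXES = {"male", "female", "unknown"}

COHORTS = ("BP", "G12", "G23", "G3")


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycle, duplicate id, bad link)."""


@dataclass(frozen=True)
class PedigreeRecord:
    """One individual: identifier, parent links and sex.

    ``sire``/``dam`` are ``None`` when unknown.  Sex is descriptive
    metadata only (boar/sow labelling in reports); no computation in the
    package depends on it.
    """

    id: str
    sire: str | None = None
    dam: str | None = None
    sex: str = "unknown"

    def __post_init__(self) -> None:
        if not self.id:
            raise PedigreeError("individual id must be non-empty")
        if self.sire == self.id or self.dam == self.id:
            raise PedigreeError(f"individual {self.id!r} is its own parent")
        if self.sex not in _SEXES:
            raise PedigreeError(f"sex must be one of {_SEXES}, got {self.sex!r}")


@dataclass(frozen=True)
class Family:
    """Offspring of one parental couple."""

    sire: str
    dam: str
    offspring: tuple[str, ...]

    @property
    def size(self) -> int:
        return len(self.offspring)


class Pedigree:
    """Validated, topologically ordered collection of :class:`PedigreeRecord`.

    Parents referenced only through ``sire``/``dam`` fields are auto-created
    as founder records (pedigree files routinely omit founder rows).
    Construction fails on duplicate identifiers and on cycles through
    parent links; the cycle error message includes the offending path.
    """

    def __init__(self, records: Iterable[PedigreeRecord]):
        self._records: dict[str, PedigreeRecord] = {}
        for rec in records:
            if rec.id in self._records:
                raise PedigreeError(f"duplicate individual id {rec.id!r}")
            self._records[rec.id] = rec
        # auto-create founders for parents without an own row
        for rec in list(self._records.values()):
            for parent, sex in ((rec.sire, "male"), (rec.dam, "female")):
                if parent is not None and parent not in self._records:
                    self._records[parent] = PedigreeRecord(id=parent, sex=sex)
        self._topo = self._toposort()

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, ind: str) -> bool:
        return ind in self._records

    def __iter__(self):
        return iter(self._topo)

    @property
    def ids(self) -> tuple[str, ...]:
        """Identifiers in topological order (parents before offspring)."""
        return self._topo

    def record(self, ind: str) -> PedigreeRecord:
        return self._records[ind]

    def parents(self, ind: str) -> tuple[str | None, str | None]:
        rec = self._records[ind]
        return rec.sire, rec.dam

    def founders(self) -> tuple[str, ...]:
        return tuple(
            i for i in self._topo
            if self._records[i].sire is None and self._records[i].dam is None
        )

    def children_of(self, ind: str) -> tuple[str, ...]:
        return tuple(
            r.id for r in self._records.values() if ind in (r.sire, r.dam)
        )

    # -- validation ---------------------------------------------------------
    def _toposort(self) -> tuple[str, ...]:
        order: list[str] = []
        state: dict[str, int] = {}  # 0 = visiting, 1 = done
        for start in self._records:
            if start in state:
                continue
            stack: list[tuple[str, int]] = [(start, 0)]
            path: list[str] = []
            while stack:
                node, phase = stack.pop()
                if phase == 0:
                    if state.get(node) == 1:
                        continue
                    if state.get(node) == 0:
                        cycle = path[path.index(node):] + [node]
                        raise PedigreeError(
                            "cycle through parent links: " + " -> ".join(cycle)
                        )
                    state[node] = 0
                    path.append(node)
                    stack.append((node, 1))
                    rec = self._records[node]
                    for parent in (rec.sire, rec.dam):
                        if parent is not None and state.get(parent) != 1:
                            stack.append((parent, 0))
                else:
                    state[node] = 1
                    path.pop()
                    order.append(node)
        return tuple(order)

    # -- conversion ---------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "id": r.id,
                "sire": r.sire or "",
                "dam": r.dam or "",
                "sex": r.sex,
            }
            for r in (self._records[i] for i in self._topo)
        ]
        return pd.DataFrame(rows, columns=["id", "sire", "dam", "sex"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        records = []
        for row in df.itertuples(index=False):
            records.append(
                PedigreeRecord(
                    id=str(row.id),
                    sire=_parse_parent(getattr(row, "sire", "")),
                    dam=_parse_parent(getattr(row, "dam", "")),
                    sex=_parse_sex(getattr(row, "sex", "unknown")),
                )
            )
        return cls(records)


def _parse_parent(token: object) -> str | None:
    token = "" if token is None else str(token).strip()
    return None if token in _UNKNOWN_TOKENS else token


def _parse_sex(token: object) -> str:
    token = str(token).strip().lower()
    if token in ("m", "male", "1"):
        return "male"
    if token in ("f", "female", "2"):
        return "female"
    return "unknown"


def load_pedigree(path: str | Path) -> Pedigree:
    """Read a pedigree CSV with header ``id,sire,dam,sex``.

    Unknown parents are encoded as an empty field or ``"0"``.  The ``sex``
    column is optional.
    """
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "id" not in reader.fieldnames:
            raise PedigreeError(f"{path}: missing header with an 'id' column")
        records = [
            PedigreeRecord(
                id=str(row["id"]).strip(),
                sire=_parse_parent(row.get("sire")),
                dam=_parse_parent(row.get("dam")),
                sex=_parse_sex(row.get("sex", "unknown")),
            )
            for row in reader
        ]
    return Pedigree(records)


def equivalent_complete_generations(ped: Pedigree) -> dict[str, float]:
    """Pedigree depth ``t`` for every individual.

    Recursion: ``t(i) = 0.5*(1 + t(sire)) + 0.5*(1 + t(dam))`` with a term
    dropped when the parent is unknown.  Founders get ``t = 0``; an
    individual with two founder parents gets ``t = 1``.
    """
    t: dict[str, float] = {}
    for ind in ped.ids:  # topological: parents first
        sire, dam = ped.parents(ind)
        value = 0.0
        if sire is not None:
            value += 0.5 * (1.0 + t[sire])
        if dam is not None:
            value += 0.5 * (1.0 + t[dam])
        t[ind] = value
    return t


def assign_cohorts(
    t_map: Mapping[str, float], bp_ids: Sequence[str]
) -> pd.DataFrame:
    """Assign every individual to exactly one cohort.

    BP membership is by the explicit ``bp_ids`` list (the base population
    mixes founders and selected descendants, so it cannot be derived from
    ``t``).  The remaining individuals split on pedigree depth with
    upper-closed boundaries: ``G12`` for ``t <= 2``, ``G23`` for
    ``2 < t <= 3``, ``G3`` for ``t > 3``.

    Returns a frame with columns ``id, t, cohort``.
    """
    missing = [i for i in bp_ids if i not in t_map]
    if missing:
        raise PedigreeError(f"BP ids absent from pedigree: {missing}")
    bp = set(bp_ids)
    rows = []
    for ind, depth in t_map.items():
        if ind in bp:
            cohort = "BP"
        elif depth <= 2:
            cohort = "G12"
        elif depth <= 3:
            cohort = "G23"
        else:
            cohort = "G3"
        rows.append({"id": ind, "t": depth, "cohort": cohort})
    return pd.DataFrame(rows, columns=["id", "t", "cohort"])


def enumerate_families(
    ped: Pedigree,
    min_offspring: int = 5,
    keep_ids: Sequence[str] = (),
    typed_ids: Sequence[str] | None = None,
) -> list[Family]:
    """Group typed offspring by parental couple.

    A family is retained when it has at least ``min_offspring`` typed
    offspring, or when any of its members (offspring or parents) appears in
    ``keep_ids`` — the escape hatch for small families that must be kept
    for pedigree continuity.  ``typed_ids`` restricts which offspring count
    as typed (default: all).
    """
    if min_offspring < 1:
        raise ValueError("min_offspring must be >= 1")
    typed = set(typed_ids) if typed_ids is not None else None
    keep = set(keep_ids)
    couples: dict[tuple[str, str], list[str]] = {}
    for ind in ped.ids:
        sire, dam = ped.parents(ind)
        if sire is None or dam is None:
            continue
        if typed is not None and ind not in typed:
            continue
        couples.setdefault((sire, dam), []).append(ind)
    families = []
    for (sire, dam), offspring in couples.items():
        members = set(offspring) | {sire, dam}
        if len(offspring) >= min_offspring or members & keep:
            families.append(Family(sire=sire, dam=dam, offspring=tuple(offspring)))
    families.sort(key=lambda f: (f.sire, f.dam))
    return families


def write_cohort_table(cohorts: pd.DataFrame, path: str | Path) -> None:
    out = cohorts.copy()
    out["t"] = out["t"].map(lambda v: f"{v:.6f}")
    out.to_csv(path, sep="\t", index=False)
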
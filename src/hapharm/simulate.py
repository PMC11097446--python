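"""Synthetic pedigrees, gene-dropped block genotypes and planted artifacts.

The generator emulates the structure of a small, densely genotyped
livestock pedigree: a founder population, a few generations of family
matings with 5–34 offspring per couple, and per-block founder haplotype
pools transmitted as intact units (no intra-block recombination — block
haplotypes behave as codominant alleles).  Two kinds of ground-truth
perturbation can be planted:

* **lethal haplotypes** — designated founder haplotypes whose homozygous
  offspring are culled at birth (drawn again), so the emitted population
  never contains a lethal homozygote while the allele itself keeps
  circulating in carriers;
* **Allele-Drop-In (ADI) errors** — genotype-call slots replaced by a
  novel allele code never present in the founder pool, emulating SNP
  calling errors.  A configurable fraction of events is *heritable*: the
  underlying artifact (think of a CNV disturbing the calls) rides along
  the true gene-drop transmission of its chromosome and expresses the
  wrong call in each carrier descendant with probability 1/2, which can
  skip a generation and produce grandparent-but-not-parent patterns.

Everything the generator plants is recorded in a machine-readable
:class:`TruthLedger`, so every downstream stage can be tested against
known truth.  All randomness flows from one :class:`numpy.random.Generator`
seeded by ``SimConfig.seed``; runs are fully reproducible.

Novel ADI codes start at 901, disjoint from the 101-based codes of real
haplotypes, so planted errors are recognizable in assertions.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alleles import FIRST_CODE, NOVEL_CODE_BASE
from .blocks import LinkageBlockDef, SnpRecord, write_block_bed
from .pedigree import Pedigree, PedigreeRecord
from . import vcfio

__all__ = [
    "LethalSpec",
    "SimConfig",
    "AdiEvent",
    "TruthLedger",
    "SyntheticDataset",
    "simulate_pedigree",
    "gene_drop",
    "apply_lethal_selection",
    "inject_adi_errors",
    "simulate_dataset",
    "write_dataset",
    "read_truth_ledger",
]


@dataclass(frozen=True)
class LethalSpec:
    """A planted lethal: haplotype ``haplotype`` of block ``block`` is
    carried (one copy) by ``carriers`` founders and kills homozygotes."""

    block: int
    haplotype: int
    carriers: int


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    Defaults mirror the study conditions the generator emulates: family
    sizes uniform on 5–34 offspring, 2–8 founder haplotypes per block.
    ``adi_rate`` is the per-(individual, block, slot) probability of a
    calling error and ``adi_heritable_fraction`` the share of errors whose
    cause is transmissible to descendants.
    """

    seed: int = 0
    n_founders: int = 10
    n_generations: int = 3
    families_per_generation: int = 4
    offspring_range: tuple[int, int] = (5, 34)
    n_blocks: int = 50
    snps_per_block: tuple[int, int] = (4, 10)
    founder_haplotypes_per_block: tuple[int, int] = (2, 8)
    lethal_spec: tuple[LethalSpec, ...] = ()
    adi_rate: float = 0.0
    adi_heritable_fraction: float = 0.0
    complementary_pools: bool = False
    chrom: str = "1"
    block_gap_bp: int = 500_000
    snp_spacing_bp: int = 1_000

    def __post_init__(self) -> None:
        if self.n_founders < 2:
            raise ValueError("need at least 2 founders")
        if not 0 <= self.adi_rate <= 1:
            raise ValueError("adi_rate must be in [0, 1]")
        if not 0 <= self.adi_heritable_fraction <= 1:
            raise ValueError("adi_heritable_fraction must be in [0, 1]")
        if self.offspring_range[0] < 1 or self.offspring_range[0] > self.offspring_range[1]:
            raise ValueError("offspring_range must be 1 <= min <= max")
        if self.founder_haplotypes_per_block[0] < 2:
            raise ValueError("need at least 2 founder haplotypes per block")
        for spec in self.lethal_spec:
            if not 0 <= spec.block < self.n_blocks:
                raise ValueError(f"lethal block {spec.block} out of range")
            if spec.carriers < 1 or spec.carriers > self.n_founders:
                raise ValueError("lethal carrier count out of range")


@dataclass(frozen=True)
class AdiEvent:
    """One expressed wrong call: ``slot`` 0 is paternal, 1 maternal.

    ``inherited`` marks expressions caused by a transmissible artifact in
    an ancestor rather than by the individual's own primary event.
    """

    individual: str
    block_id: str
    slot: int
    original: int
    wrong: int
    heritable: bool
    inherited: bool = False


@dataclass
class TruthLedger:
    """Machine-readable record of everything the generator planted."""

    planted_lethals: list[dict] = field(default_factory=list)
    adi_events: list[AdiEvent] = field(default_factory=list)
    n_lethal_redraws: int = 0

    def adi_individuals(self) -> set[str]:
        return {e.individual for e in self.adi_events}

    def to_json(self) -> str:
        return json.dumps(
            {
                "planted_lethals": self.planted_lethals,
                "adi_events": [dataclasses.asdict(e) for e in self.adi_events],
                "n_lethal_redraws": self.n_lethal_redraws,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "TruthLedger":
        raw = json.loads(text)
        return cls(
            planted_lethals=raw["planted_lethals"],
            adi_events=[AdiEvent(**e) for e in raw["adi_events"]],
            n_lethal_redraws=raw["n_lethal_redraws"],
        )


@dataclass
class SyntheticDataset:
    """A complete simulated dataset plus its ground truth."""

    cfg: SimConfig
    ped: Pedigree
    individuals: list[str]  # genotype row order
    snps: list[SnpRecord]
    blocks: list[LinkageBlockDef]
    haplotypes: np.ndarray  # (2N, S) 0/1, consistent with `genotypes`
    genotypes: pd.DataFrame  # individual, block_id, allele1, allele2
    registry: pd.DataFrame  # block_id, code, haplotype
    ledger: TruthLedger


# ---------------------------------------------------------------------------
# pedigree simulation
# ---------------------------------------------------------------------------

def simulate_pedigree(cfg: SimConfig) -> Pedigree:
    """Multi-generation pedigree with family matings.

    Founders alternate male/female.  Each generation,
    ``families_per_generation`` couples are formed from the previous
    generation (sires and dams sampled without replacement) and each
    couple produces a uniform 5–34 (configurable) number of offspring
    with alternating sexes.  Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(cfg.seed)
    records: list[PedigreeRecord] = []
    males: list[str] = []
    females: list[str] = []
    for k in range(cfg.n_founders):
        sex = "male" if k % 2 == 0 else "female"
        ind = f"F{k + 1:03d}"
        records.append(PedigreeRecord(id=ind, sex=sex))
        (males if sex == "male" else females).append(ind)

    lo, hi = cfg.offspring_range
    for gen in range(1, cfg.n_generations + 1):
        n_fam = cfg.families_per_generation
        if n_fam > min(len(males), len(females)):
            raise ValueError(
                f"generation {gen}: cannot form {n_fam} couples from "
                f"{len(males)} males and {len(females)} females"
            )
        sires = rng.permutation(males)[:n_fam]
        dams = rng.permutation(females)[:n_fam]
        next_males: list[str] = []
        next_females: list[str] = []
        child_no = 0
        for sire, dam in zip(sires, dams):
            n_off = int(rng.integers(lo, hi + 1))
            for j in range(n_off):
                child_no += 1
                sex = "male" if j % 2 == 0 else "female"
                ind = f"G{gen}_{child_no:04d}"
                records.append(
                    PedigreeRecord(id=ind, sire=str(sire), dam=str(dam), sex=sex)
                )
                (next_males if sex == "male" else next_females).append(ind)
        males, females = next_males, next_females
    return Pedigree(records)


# ---------------------------------------------------------------------------
# gene drop
# ---------------------------------------------------------------------------

def _build_blocks(cfg: SimConfig, rng: np.random.Generator):
    """Per-block SNP maps and founder haplotype pools (0/1 matrices)."""
    snps: list[SnpRecord] = []
    blocks: list[LinkageBlockDef] = []
    pools: list[np.ndarray] = []
    for b in range(cfg.n_blocks):
        n_snps = int(rng.integers(cfg.snps_per_block[0], cfg.snps_per_block[1] + 1))
        start = 1 + b * cfg.block_gap_bp
        first = len(snps)
        for k in range(n_snps):
            snps.append(
                SnpRecord(
                    chrom=cfg.chrom,
                    pos=start + k * cfg.snp_spacing_bp,
                    id=f"B{b}S{k}",
                )
            )
        blocks.append(
            LinkageBlockDef(
                block_id=f"LB{b + 1}",
                chrom=cfg.chrom,
                start_bp=snps[first].pos,
                end_bp=snps[-1].pos,
                snp_indices=tuple(range(first, first + n_snps)),
            )
        )
        pool_size = int(
            rng.integers(
                cfg.founder_haplotypes_per_block[0],
                cfg.founder_haplotypes_per_block[1] + 1,
            )
        )
        pool_size = min(pool_size, 2 ** n_snps)
        if cfg.complementary_pools:
            base = rng.integers(0, 2, size=n_snps, dtype=np.uint8)
            pool = np.stack([base, 1 - base])[:pool_size]
            if pool_size != 2:
                raise ValueError("complementary_pools requires pool size 2")
        else:
            ints = rng.choice(2 ** n_snps, size=pool_size, replace=False)
            pool = (
                (ints[:, None] >> np.arange(n_snps)[None, :]) & 1
            ).astype(np.uint8)
        pools.append(pool)
    return snps, blocks, pools


def _assign_founder_haplotypes(
    cfg: SimConfig, pools: Sequence[np.ndarray], rng: np.random.Generator
) -> np.ndarray:
    """(n_founders, n_blocks, 2) pool indices with planted lethal carriers."""
    n_f = cfg.n_founders
    geno = np.empty((n_f, cfg.n_blocks, 2), dtype=np.int16)
    lethal_by_block = {s.block: s for s in cfg.lethal_spec}
    for b in range(cfg.n_blocks):
        pool_size = len(pools[b])
        spec = lethal_by_block.get(b)
        if spec is None:
            geno[:, b, :] = rng.integers(0, pool_size, size=(n_f, 2))
            continue
        if spec.haplotype >= pool_size:
            raise ValueError(
                f"lethal haplotype index {spec.haplotype} exceeds pool of "
                f"block {b}"
            )
        others = [h for h in range(pool_size) if h != spec.haplotype]
        geno[:, b, :] = rng.choice(others, size=(n_f, 2))
        carrier_ix = rng.choice(n_f, size=spec.carriers, replace=False)
        slots = rng.integers(0, 2, size=spec.carriers)
        geno[carrier_ix, b, slots] = spec.haplotype
    return geno


def apply_lethal_selection(
    rng: np.random.Generator,
    father: np.ndarray,
    mother: np.ndarray,
    lethal_by_block: Mapping[int, int],
    max_redraws: int = 100_000,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Draw one viable offspring from a couple, culling lethal homozygotes.

    ``father``/``mother`` are (n_blocks, 2) allele arrays.  Any draw
    homozygous for a planted lethal haplotype at its block is discarded
    and redrawn; the redraw count is returned.  A couple in which both
    parents are homozygous lethal carriers cannot produce viable
    offspring and is a fatal error.

    Returns ``(child_alleles, child_trace, n_redraws)`` where
    ``child_trace[b, s]`` is the parental slot (0/1) that was transmitted
    into the child's slot ``s`` at block ``b``.
    """
    n_blocks = father.shape[0]
    for b, lethal in lethal_by_block.items():
        if (father[b] == lethal).all() and (mother[b] == lethal).all():
            raise ValueError(
                f"block {b}: both parents homozygous for lethal haplotype "
                f"{lethal}; no viable offspring possible"
            )
    n_redraws = 0
    while True:
        trace = rng.integers(0, 2, size=(n_blocks, 2), dtype=np.int8)
        child = np.empty((n_blocks, 2), dtype=father.dtype)
        child[:, 0] = father[np.arange(n_blocks), trace[:, 0]]
        child[:, 1] = mother[np.arange(n_blocks), trace[:, 1]]
        dead = any(
            child[b, 0] == lethal and child[b, 1] == lethal
            for b, lethal in lethal_by_block.items()
        )
        if not dead:
            return child, trace, n_redraws
        n_redraws += 1
        if n_redraws > max_redraws:
            raise RuntimeError("redraw budget exhausted during lethal culling")


def gene_drop(
    ped: Pedigree, cfg: SimConfig, rng: np.random.Generator | None = None
):
    """Drop founder block haplotypes down the pedigree.

    Each offspring receives, per block, one haplotype chosen uniformly
    from each parent's pair; blocks are transmitted as intact units.
    Offspring homozygous for a planted lethal are culled and redrawn.

    Returns ``(individuals, snps, blocks, pools, geno, trace, ledger)``
    where ``geno[i, b, s]`` is a founder-pool index and ``trace`` records
    which parental slot fed each offspring slot (-1 for founders).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    snps, blocks, pools = _build_blocks(cfg, rng)
    individuals = list(ped.ids)
    ind_ix = {v: k for k, v in enumerate(individuals)}
    n = len(individuals)
    if len(ped.founders()) != cfg.n_founders:
        raise ValueError(
            f"pedigree has {len(ped.founders())} founders but the "
            f"configuration expects {cfg.n_founders}"
        )
    geno = np.empty((n, cfg.n_blocks, 2), dtype=np.int16)
    trace = np.full((n, cfg.n_blocks, 2), -1, dtype=np.int8)
    founder_geno = _assign_founder_haplotypes(cfg, pools, rng)
    lethal_by_block = {s.block: s.haplotype for s in cfg.lethal_spec}

    ledger = TruthLedger(
        planted_lethals=[
            {
                "block_id": blocks[s.block].block_id,
                "code": FIRST_CODE + s.haplotype,
                "haplotype": "".join(map(str, pools[s.block][s.haplotype])),
                "founder_carriers": s.carriers,
            }
            for s in cfg.lethal_spec
        ]
    )

    founder_no = 0
    for ind in individuals:
        sire, dam = ped.parents(ind)
        i = ind_ix[ind]
        if sire is None and dam is None:
            geno[i] = founder_geno[founder_no]
            founder_no += 1
        elif sire is None or dam is None:
            raise ValueError(f"{ind}: simulation requires both parents or none")
        else:
            child, tr, redraws = apply_lethal_selection(
                rng, geno[ind_ix[sire]], geno[ind_ix[dam]], lethal_by_block
            )
            geno[i] = child
            trace[i] = tr
            ledger.n_lethal_redraws += redraws
    return individuals, snps, blocks, pools, geno, trace, ledger


# ---------------------------------------------------------------------------
# Allele-Drop-In injection
# ---------------------------------------------------------------------------

def inject_adi_errors(
    codes: np.ndarray,
    ped: Pedigree,
    individuals: Sequence[str],
    blocks: Sequence[LinkageBlockDef],
    trace: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
    ledger: TruthLedger,
) -> np.ndarray:
    """Mutate genotype calls with random and heritable ADI events.

    ``codes`` is the (N, n_blocks, 2) allele-code array; a mutated copy is
    returned and every expressed wrong call is appended to ``ledger``.

    Each slot is independently hit with probability ``cfg.adi_rate`` and
    receives a fresh novel code (>= 901, unique per event within its
    block).  With probability ``cfg.adi_heritable_fraction`` the event's
    cause is transmissible: descendants who inherited that chromosome
    copy (known from the gene-drop trace) carry the artifact, and each
    carrier expresses the wrong call with probability 1/2 — silent
    carriers still pass the artifact on, so expression can skip a
    generation.
    """
    if cfg.adi_rate == 0:
        return codes
    out = codes.copy()
    ind_ix = {v: k for k, v in enumerate(individuals)}
    children: dict[str, list[tuple[str, int]]] = {ind: [] for ind in individuals}
    for ind in individuals:
        sire, dam = ped.parents(ind)
        if sire is not None:
            children[sire].append((ind, 0))
        if dam is not None:
            children[dam].append((ind, 1))

    novel_next = [NOVEL_CODE_BASE + 1] * len(blocks)
    hits = np.argwhere(rng.random(out.shape) < cfg.adi_rate)
    for i, b, s in hits:
        wrong = novel_next[b]
        novel_next[b] += 1
        heritable = bool(rng.random() < cfg.adi_heritable_fraction)
        ledger.adi_events.append(
            AdiEvent(
                individual=individuals[i],
                block_id=blocks[b].block_id,
                slot=int(s),
                original=int(out[i, b, s]),
                wrong=wrong,
                heritable=heritable,
            )
        )
        out[i, b, s] = wrong
        if not heritable:
            continue
        # propagate the artifact along the true transmission lineage
        stack = [(individuals[i], int(s))]
        while stack:
            carrier, slot = stack.pop()
            for child, child_slot in children[carrier]:
                ci = ind_ix[child]
                if trace[ci, b, child_slot] != slot:
                    continue  # child inherited the other chromosome copy
                if rng.random() < 0.5:
                    ledger.adi_events.append(
                        AdiEvent(
                            individual=child,
                            block_id=blocks[b].block_id,
                            slot=child_slot,
                            original=int(out[ci, b, child_slot]),
                            wrong=wrong,
                            heritable=True,
                            inherited=True,
                        )
                    )
                    out[ci, b, child_slot] = wrong
                stack.append((child, child_slot))
    return out


# ---------------------------------------------------------------------------
# top-level dataset assembly and I/O
# ---------------------------------------------------------------------------

def simulate_dataset(cfg: SimConfig) -> SyntheticDataset:
    """Pedigree + gene drop + lethal culling + ADI, as one dataset."""
    ped = simulate_pedigree(cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    individuals, snps, blocks, pools, geno, trace, ledger = gene_drop(ped, cfg, rng)

    codes = (geno + FIRST_CODE).astype(np.int16)
    codes = inject_adi_errors(
        codes, ped, individuals, blocks, trace, cfg, rng, ledger
    )

    # registry: founder haplotypes plus one novel haplotype per ADI code
    reg_rows = []
    novel_haps: list[dict[int, np.ndarray]] = []
    for b, blk in enumerate(blocks):
        for h, hap in enumerate(pools[b]):
            reg_rows.append(
                {
                    "block_id": blk.block_id,
                    "code": FIRST_CODE + h,
                    "haplotype": "".join(map(str, hap)),
                }
            )
        seen = {hap.tobytes() for hap in pools[b]}
        per_block: dict[int, np.ndarray] = {}
        for code in np.unique(codes[:, b, :]):
            if code < NOVEL_CODE_BASE:
                continue
            n_snps = blk.n_snps
            while True:
                hap = rng.integers(0, 2, size=n_snps, dtype=np.uint8)
                if hap.tobytes() not in seen:
                    seen.add(hap.tobytes())
                    break
            per_block[int(code)] = hap
            reg_rows.append(
                {
                    "block_id": blk.block_id,
                    "code": int(code),
                    "haplotype": "".join(map(str, hap)),
                }
            )
        novel_haps.append(per_block)
    registry = pd.DataFrame(reg_rows, columns=["block_id", "code", "haplotype"])

    # SNP haplotype matrix consistent with the (possibly mutated) calls
    n = len(individuals)
    n_snps_total = len(snps)
    hap = np.empty((2 * n, n_snps_total), dtype=np.uint8)
    for b, blk in enumerate(blocks):
        cols = list(blk.snp_indices)
        for i in range(n):
            for s in (0, 1):
                code = int(codes[i, b, s])
                if code < NOVEL_CODE_BASE:
                    hap[2 * i + s, cols] = pools[b][code - FIRST_CODE]
                else:
                    hap[2 * i + s, cols] = novel_haps[b][code]

    genotypes = pd.DataFrame(
        {
            "individual": np.repeat(individuals, len(blocks)),
            "block_id": np.tile([b.block_id for b in blocks], n),
            "allele1": codes[:, :, 0].ravel(),
            "allele2": codes[:, :, 1].ravel(),
        }
    )
    return SyntheticDataset(
        cfg=cfg,
        ped=ped,
        individuals=individuals,
        snps=snps,
        blocks=blocks,
        haplotypes=hap,
        genotypes=genotypes,
        registry=registry,
        ledger=ledger,
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the dataset as plain-text files; round-trips losslessly.

    Emits pedigree CSV, phased VCF, block-genotype TSV, block BED, allele
    registry TSV and truth-ledger JSON.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "pedigree": outdir / "pedigree.csv",
        "vcf": outdir / "genotypes.vcf",
        "block_genotypes": outdir / "block_genotypes.tsv",
        "blocks_bed": outdir / "blocks.bed",
        "registry": outdir / "allele_registry.tsv",
        "truth": outdir / "truth.json",
    }
    ds.ped.to_frame().to_csv(paths["pedigree"], index=False)
    vcfio.write_phased_vcf(paths["vcf"], ds.snps, ds.haplotypes, ds.individuals)
    ds.genotypes.to_csv(paths["block_genotypes"], sep="\t", index=False)
    write_block_bed(ds.blocks, paths["blocks_bed"])
    ds.registry.to_csv(paths["registry"], sep="\t", index=False)
    paths["truth"].write_text(ds.ledger.to_json())
    return paths


def read_block_genotypes(path: str | Path) -> pd.DataFrame:
    """Read a block-genotype TSV (individual, block_id, allele1, allele2)."""
    df = pd.read_csv(path, sep="\t", dtype={"individual": str, "block_id": str})
    required = {"individual", "block_id", "allele1", "allele2"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    return df


def read_truth_ledger(path: str | Path) -> TruthLedger:
    return TruthLedger.from_json(Path(path).read_text())
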
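# Methods

## Problem and model

`hapharm` analyzes a densely genotyped livestock pedigree for
*potentially harmful haplotypes*: within-block haplotypes at low
frequency that are never observed homozygous, the classical signature of
a recessive lethal. Because the same signature is produced by
genotype-calling artifacts — Allele-Drop-In (ADI) events, alleles present
in an offspring's calls but in neither parent — the package pairs the
frequency scan with a Mendelian audit and an ancestor-trail
classification that separates verifiable segregants from artifacts.

The analysis treats each linkage block (LB) as a single codominant,
microsatellite-like locus whose alleles are the distinct phased SNP
strings observed within the block. This is valid to the extent that
recombination inside blocks is negligible over the depth of the pedigree,
which is why block spans are capped (default 400 kb, the average extent
of LD in pig).

## Pipeline stages

**Pedigree depth and cohorts.** Pedigree depth is measured in
equivalents to complete generations,
`t(i) = 0.5·(1 + t(sire)) + 0.5·(1 + t(dam))` with unknown-parent terms
dropped. Cohorts: an explicit base-population (BP) id list, then
`G12` (t ≤ 2), `G23` (2 < t ≤ 3), `G3` (t > 3); the boundaries are
upper-closed. BP is an explicit list because real base populations mix
founders with selected descendants; it defaults to the pedigree founders.

**Block detection.** Gabriel-style confidence-interval blocks on phased
data. For each SNP pair the multinomial likelihood of the observed
haplotype counts is profiled over a |D′| grid (step 0.001) with allele
frequencies fixed at sample values; the 5th/95th cumulative-likelihood
grid points are the CI bounds (central mass 0.90). Pairs are strong LD
when `ci_high ≥ 0.98` and `ci_low ≥ 0.70`, strong recombination when
`ci_high < 0.90`. Candidate blocks need a strong-LD outermost pair, span
≤ 400 kb, and ≥ 95 % strong-LD among informative internal pairs; they
are accepted longest-span first (leftmost tie-break), discarding
overlaps. Because input is phased, haplotype counts are exact and the EM
step of the unphased algorithm is unnecessary. Block length is
`end − start` (not `+1`), matching the convention of published block
tables. No MAF filter is applied before block finding.

**Allele coding.** Per block, haplotype strings are numbered from 101 in
first-observation order (individuals in input order, paternal slot before
maternal). The coding is arbitrary by construction; only the partition of
haplotypes matters, and tests assert the partition is invariant to
individual order. Codes ≥ 900 are reserved for synthetic error alleles.

**Candidate scan.** For an allele at frequency `q = copies/2N` among `N`
individuals, `E[H] = q²N` and `P(O[H]=0 | E[H]) = exp(−E[H])`. Two
directions are provided because the two inequality readings answer
different questions:

* `rare` (default): flag `p_zero > 1 − α`. This reproduces descriptive
  candidate tables built on small pedigrees — at α = 0.05 and N = 471 the
  admissible copy count tops out at 9, and homozygote carriers are not
  excluded.
* `depleted`: flag `p_zero < α` with zero observed homozygotes — the
  statistically powered recessive-lethal scan.

α is applied as a strict inequality; no multiple-testing correction is
performed. `N` counts individuals, not chromosomes.

**Mendelian audit.** A trio is consistent when one offspring allele can
come from the father's pair and the other from the mother's. Offspring
alleles absent from both parents are counted one mismatch per slot and
attributed to the offspring (the ADI signature). When all offspring
alleles exist in some parent but no joint assignment works, one mismatch
is attributed to the parent that transmits nothing. Rates follow the
parentage-testing convention: `e_a = m_a/2nt`, `e_l = m_l/nt`, with
`nt` = (offspring with both parents genotyped) × loci. The fraction of
loci carrying any inconsistency is reported separately (`lb_fraction`)
because it is a different quantity from `e_l` despite often being quoted
in the same breath. Individuals lacking a genotyped parent contribute no
trios.

**Segregation classes.** Per candidate allele, presence flags in
carriers' fathers, mothers, paternal grandparents and maternal
grandparents are OR-ed over all carriers; untyped ancestors contribute
false. Classes: `de_novo` (no flag), `parent_only`, `grandparent_only`,
`parent_and_grandparent`, and `segregant` (all four flags — the only
class treated as a trustworthy harmful-allele call). Grandparent flags
deliberately do not require the connecting parent to carry the allele:
transmission gaps are the artifact signature this classification exists
to expose. The check stops at grandparents; deeper trails add little
once a two-generation trail exists.

**Interval overlaps.** Recombination hotspots are windows with
`ρ > mean + 2.5·sd` (population s.d., genome-wide baseline by default;
per-chromosome behind a flag). Blocks are intersected with hotspot
windows and CNV regions with half-open coordinates, converting the
1-based block coordinates on ingest (`start − 1`), so results match
`bedtools intersect`.

## Synthetic data generator

The generator emulates a multi-family livestock pedigree: founders,
`n_generations` rounds of couples drawn from the previous generation,
family sizes uniform on 5–34 offspring (the range observed in the kind of
conservation-programme pedigree this package targets). Per block, a
founder pool of 2–8 distinct haplotypes is built; offspring receive one
haplotype per block from each parent with no intra-block recombination.
All randomness flows from a single seeded generator.

Planted truth, recorded in a JSON ledger:

* **Lethals** — designated founder haplotypes with an exact founder
  carrier count; homozygous offspring are culled and redrawn, so the
  emitted population has zero lethal homozygotes while carriers persist.
* **ADI errors** — each (individual, block, slot) is hit with probability
  `adi_rate` and replaced by a fresh novel code (≥ 901, with a matching
  novel SNP string so the emitted VCF stays consistent with the block
  table). A fraction `adi_heritable_fraction` of events is transmissible:
  the artifact rides the true transmission of its chromosome copy and
  expresses the wrong call with probability 1/2 in each carrier
  descendant. Silent carriers still transmit, so expression can skip a
  generation — the mechanism that produces grandparent-present /
  parent-absent patterns, as CNV-driven calling errors do in real arrays.

`adi_rate` defaults to 0 (clean data); error injection is opt-in. What
the generator does **not** model: intra-block recombination, sequence
mutation, array-intensity noise, imputation errors as a distinct process
(ADI subsumes them), or assortative/overlapping-generation matings.
Passing tests on this generator therefore demonstrate correctness of the
bookkeeping and the statistical machinery under idealized Mendelian
transmission, not robustness to every artifact of real array data.

## Numerical choices and degenerate inputs

* D′ grid step 0.001, fixed for reproducibility; monomorphic pairs are
  classified uninformative rather than given numeric output.
* Lethal culling redraws are capped (10⁵) to turn an impossible mating
  into an error instead of a hang; a couple of two homozygous lethal
  carriers is rejected up front.
* Cohort boundaries are closed above; BP ids absent from the pedigree
  are fatal; pedigree cycles are fatal with the cycle path in the
  message.
* `q = copies/2N` with `N` = genotyped individuals in scope, forced by
  the arithmetic of single-copy alleles (1/942 at N = 471).

## Problem sizes used in tests and the acceptance script

Simulated datasets are kept at desk scale so the whole suite runs in
seconds on one core: property datasets use 12–20 founders, 2–3
generations, 25–120 blocks (≈100–500 individuals); the planted-lethal
power estimate uses 100 replicates of a one-block population of ≈480
individuals with founder lethal frequency 0.10, which gives ≥ 0.9
detection power for the `depleted` scan; the trio-consistency oracle is
exercised on 10⁵ random trios. These sizes are the package's own test
conditions, chosen to make binomial tolerances (±3 s.d.) meaningful.

## Known limitations

* The parent-attribution rule is a deterministic convention; a
  likelihood-based parentage engine may attribute ambiguous trios
  differently.
* Block detection omits Haploview's marker-count-dependent CI
  adjustments; thresholds are fixed defaults, exposed in configuration.
* The `rare` direction is descriptive, not a hypothesis test: it flags
  alleles whose homozygote absence is *expected*, and inherits all the
  sample-size sensitivity that implies.
* Real base populations are defined by breeding history; the default
  BP = founders is a stand-in, and any explicit id list should be
  preferred when available.
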
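"""Synthetic data generator: determinism, Mendelian structure, lethal
culling, Allele-Drop-In injection and file round-trips."""

import numpy as np
import pytest

from hapharm.alleles import NOVEL_CODE_BASE
from hapharm.pedigree import load_pedigree
from hapharm.simulate import (
    LethalSpec,
    SimConfig,
    apply_lethal_selection,
    read_block_genotypes,
    read_truth_ledger,
    simulate_dataset,
    simulate_pedigree,
    write_dataset,
)
from hapharm.vcfio import read_phased_vcf


class TestSimulatePedigree:
    def test_deterministic_under_seed(self):
        cfg = SimConfig(seed=1, n_founders=4, n_generations=2,
                        families_per_generation=2, offspring_range=(5, 9))
        a = simulate_pedigree(cfg).to_frame()
        b = simulate_pedigree(cfg).to_frame()
        assert a.equals(b)

    def test_zero_generations_gives_founders_only(self):
        cfg = SimConfig(seed=1, n_founders=6, n_generations=0)
        ped = simulate_pedigree(cfg)
        assert len(ped) == 6
        assert set(ped.founders()) == set(ped.ids)

    def test_fixed_family_size_counts(self):
        cfg = SimConfig(seed=2, n_founders=6, n_generations=2,
                        families_per_generation=3, offspring_range=(5, 5))
        ped = simulate_pedigree(cfg)
        # 6 founders + 15 per generation
        assert len(ped) == 6 + 2 * 15

    def test_every_nonfounder_has_both_parents(self):
        cfg = SimConfig(seed=3, n_founders=8, n_generations=3,
                        families_per_generation=3, offspring_range=(5, 8))
        ped = simulate_pedigree(cfg)
        for ind in ped.ids:
            sire, dam = ped.parents(ind)
            assert (sire is None) == (dam is None)


class TestGeneDrop:
    def test_opposite_homozygotes_give_uniform_heterozygotes(self):
        rng = np.random.default_rng(0)
        father = np.array([[0, 0]])
        mother = np.array([[1, 1]])
        for _ in range(50):
            child, _, redraws = apply_lethal_selection(rng, father, mother, {})
            assert sorted(child[0]) == [0, 1]
            assert redraws == 0

    def test_transmission_is_binomial(self):
        # het x hom: transmitted allele from the het parent ~ Binomial(n, 1/2)
        rng = np.random.default_rng(1)
        father = np.array([[0, 1]])
        mother = np.array([[2, 2]])
        n = 1000
        hits = sum(
            apply_lethal_selection(rng, father, mother, {})[0][0, 0] == 0
            for _ in range(n)
        )
        sd = np.sqrt(n * 0.25)
        assert abs(hits - n / 2) <= 3 * sd

    def test_no_novel_codes_without_adi(self, clean_ds):
        assert clean_ds.genotypes[["allele1", "allele2"]].to_numpy().max() \
            < NOVEL_CODE_BASE

    def test_descendant_alleles_subset_of_founder_pool(self, clean_ds):
        founders = set(clean_ds.ped.founders())
        g = clean_ds.genotypes
        for block_id, grp in g.groupby("block_id"):
            fo = grp[grp["individual"].isin(founders)]
            de = grp[~grp["individual"].isin(founders)]
            f_codes = set(fo["allele1"]) | set(fo["allele2"])
            d_codes = set(de["allele1"]) | set(de["allele2"])
            assert d_codes <= f_codes


class TestLethalSelection:
    def test_carrier_cross_redraw_fraction(self):
        rng = np.random.default_rng(5)
        father = np.array([[0, 1]])
        mother = np.array([[0, 2]])
        n = 1000
        children = []
        total_redraws = 0
        for _ in range(n):
            child, _, r = apply_lethal_selection(rng, father, mother, {0: 0})
            children.append(child)
            total_redraws += r
        # no lethal homozygote ever emitted
        assert not any((c[0] == 0).all() for c in children)
        # redraw fraction ~ 1/4 of all draws
        draws = n + total_redraws
        sd = np.sqrt(draws * 0.25 * 0.75)
        assert abs(total_redraws - draws * 0.25) <= 3 * sd

    def test_noncarrier_cross_never_redraws(self):
        rng = np.random.default_rng(6)
        father = np.array([[1, 2]])
        mother = np.array([[1, 2]])
        for _ in range(100):
            assert apply_lethal_selection(rng, father, mother, {0: 0})[2] == 0

    def test_carrier_by_noncarrier_offspring_half_carriers(self):
        rng = np.random.default_rng(7)
        father = np.array([[0, 1]])
        mother = np.array([[2, 2]])
        n = 1000
        carriers = sum(
            0 in apply_lethal_selection(rng, father, mother, {0: 0})[0][0]
            for _ in range(n)
        )
        sd = np.sqrt(n * 0.25)
        assert abs(carriers - n / 2) <= 3 * sd

    def test_double_homozygote_couple_is_fatal(self):
        rng = np.random.default_rng(8)
        father = np.array([[0, 0]])
        mother = np.array([[0, 0]])
        with pytest.raises(ValueError, match="no viable offspring"):
            apply_lethal_selection(rng, father, mother, {0: 0})

    def test_no_lethal_homozygotes_in_emitted_dataset(self):
        cfg = SimConfig(seed=21, n_founders=20, n_generations=2,
                        families_per_generation=8, offspring_range=(5, 10),
                        n_blocks=4,
                        lethal_spec=(LethalSpec(block=1, haplotype=0,
                                                carriers=6),))
        ds = simulate_dataset(cfg)
        lethal = ds.ledger.planted_lethals[0]
        g = ds.genotypes
        hom = g[(g["block_id"] == lethal["block_id"])
                & (g["allele1"] == lethal["code"])
                & (g["allele2"] == lethal["code"])]
        assert len(hom) == 0


class TestAdiInjection:
    def test_zero_rate_changes_nothing(self, clean_ds):
        assert clean_ds.ledger.adi_events == []

    def test_rate_one_replaces_every_slot(self):
        cfg = SimConfig(seed=9, n_founders=2, n_generations=0, n_blocks=3,
                        adi_rate=1.0)
        ds = simulate_dataset(cfg)
        codes = ds.genotypes[["allele1", "allele2"]].to_numpy()
        assert (codes >= NOVEL_CODE_BASE).all()

    def test_event_count_within_binomial_bounds(self):
        rate = 0.002
        cfg = SimConfig(seed=10, n_founders=20, n_generations=2,
                        families_per_generation=10, offspring_range=(20, 28),
                        n_blocks=60, adi_rate=rate)
        ds = simulate_dataset(cfg)
        slots = len(ds.individuals) * len(ds.blocks) * 2
        expected = rate * slots
        sd = np.sqrt(slots * rate * (1 - rate))
        assert abs(len(ds.ledger.adi_events) - expected) <= 3 * sd

    def test_events_reference_existing_individuals_and_blocks(self, adi_ds):
        inds = set(adi_ds.individuals)
        block_ids = {b.block_id for b in adi_ds.blocks}
        for e in adi_ds.ledger.adi_events:
            assert e.individual in inds
            assert e.block_id in block_ids
            assert e.wrong > NOVEL_CODE_BASE
            assert e.slot in (0, 1)


class TestWriteDataset:
    def test_round_trip(self, tmp_path, adi_ds):
        paths = write_dataset(adi_ds, tmp_path)
        ped2 = load_pedigree(paths["pedigree"])
        assert set(ped2.ids) == set(adi_ds.ped.ids)
        geno2 = read_block_genotypes(paths["block_genotypes"])
        assert geno2.equals(
            adi_ds.genotypes.astype(
                {"allele1": geno2["allele1"].dtype,
                 "allele2": geno2["allele2"].dtype}
            )
        )
        snps, hap, samples = read_phased_vcf(paths["vcf"])
        assert samples == adi_ds.individuals
        assert np.array_equal(hap, adi_ds.haplotypes)
        assert [(s.chrom, s.pos) for s in snps] == \
            [(s.chrom, s.pos) for s in adi_ds.snps]
        ledger2 = read_truth_ledger(paths["truth"])
        assert ledger2 == adi_ds.ledger

    def test_vcf_positions_sorted(self, tmp_path, clean_ds):
        paths = write_dataset(clean_ds, tmp_path)
        snps, _, _ = read_phased_vcf(paths["vcf"])
        pos = [s.pos for s in snps]
        assert pos == sorted(pos)

    def test_bed_interval_count_matches_blocks(self, tmp_path, clean_ds):
        paths = write_dataset(clean_ds, tmp_path)
        lines = [l for l in paths["blocks_bed"].read_text().splitlines() if l]
        assert len(lines) == len(clean_ds.blocks)
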
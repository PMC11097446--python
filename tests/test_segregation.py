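"""Ancestor-presence flags, segregation classes and the Venn tally."""

import pandas as pd
import pytest

from hapharm.pedigree import Pedigree, PedigreeRecord
from hapharm.segregation import (
    AncestorPresence,
    GenotypeLookup,
    ancestor_presence,
    carrier_pedigree_dot,
    classify_allele_segregation,
    trace_alleles,
    venn_table,
)


def _geno(rows):
    return pd.DataFrame(rows, columns=["individual", "block_id",
                                       "allele1", "allele2"])


def _presence(f=False, m=False, pgp=False, mgp=False):
    return AncestorPresence("LB1", 102, f, m, pgp, mgp, 1, 1)


class TestClassify:
    @pytest.mark.parametrize(
        "flags, expected",
        [
            (dict(), "de_novo"),
            (dict(f=True, m=True, pgp=True, mgp=True), "segregant"),
            (dict(m=True), "parent_only"),
            (dict(f=True, m=True), "parent_only"),
            (dict(pgp=True), "grandparent_only"),
            (dict(pgp=True, mgp=True), "grandparent_only"),
            (dict(f=True, pgp=True), "parent_and_grandparent"),
            (dict(f=True, m=True, pgp=True), "parent_and_grandparent"),
            (dict(f=True, mgp=True), "parent_and_grandparent"),
        ],
    )
    def test_rules(self, flags, expected):
        assert classify_allele_segregation(_presence(**flags)) == expected


def _three_gen_pedigree():
    """Founder couple -> daughter (with founder mate) -> grandsons."""
    rows = [
        PedigreeRecord("gpf", sex="male"),
        PedigreeRecord("gpm", sex="female"),
        PedigreeRecord("mate", sex="male"),
        PedigreeRecord("daughter", sire="gpf", dam="gpm", sex="female"),
    ]
    rows += [
        PedigreeRecord(f"son{k}", sire="mate", dam="daughter", sex="male")
        for k in range(5)
    ]
    return Pedigree(rows)


class TestAncestorPresence:
    def test_founder_only_carrier_has_no_flags(self):
        ped = Pedigree([PedigreeRecord("solo")])
        lookup = GenotypeLookup(_geno([("solo", "LB1", 102, 101)]))
        pres = ancestor_presence("LB1", 102, lookup, ped)
        assert not any(
            [pres.in_father, pres.in_mother, pres.in_pgp, pres.in_mgp]
        )
        assert pres.carrier_count == 1

    def test_founder_to_daughter_to_grandsons_trail(self):
        """A true transmission trail lights the parent flag and the
        matching grandparent flag of the grandson carriers."""
        ped = _three_gen_pedigree()
        rows = [("gpf", "LB1", 102, 101), ("gpm", "LB1", 101, 101),
                ("mate", "LB1", 101, 101),
                ("daughter", "LB1", 102, 101)]
        rows += [(f"son{k}", "LB1", 101, 102) for k in range(5)]
        lookup = GenotypeLookup(_geno(rows))
        pres = ancestor_presence("LB1", 102, lookup, ped)
        assert pres.in_mother        # the sons' mother (daughter) carries
        assert pres.in_mgp           # gpf is the sons' maternal grandfather
        assert pres.in_father        # daughter is a carrier too; her father carries
        assert not pres.in_pgp       # nobody's paternal grandparents carry
        assert classify_allele_segregation(pres) == "parent_and_grandparent"

    def test_de_novo_in_sibship_with_noncarrier_parents(self):
        ped = _three_gen_pedigree()
        rows = [("gpf", "LB1", 101, 101), ("gpm", "LB1", 101, 101),
                ("mate", "LB1", 101, 101), ("daughter", "LB1", 101, 101)]
        rows += [(f"son{k}", "LB1", 101, 106) for k in range(5)]
        lookup = GenotypeLookup(_geno(rows))
        pres = ancestor_presence("LB1", 106, lookup, ped)
        assert not any(
            [pres.in_father, pres.in_mother, pres.in_pgp, pres.in_mgp]
        )
        assert classify_allele_segregation(pres) == "de_novo"

    def test_untyped_ancestors_contribute_false(self):
        ped = Pedigree([
            PedigreeRecord("f", sex="male"),
            PedigreeRecord("m", sex="female"),
            PedigreeRecord("c", sire="f", dam="m"),
        ])
        # parents in pedigree but never genotyped
        lookup = GenotypeLookup(_geno([("c", "LB1", 102, 101)]))
        pres = ancestor_presence("LB1", 102, lookup, ped)
        assert not pres.in_father and not pres.in_mother


class TestCleanTransmission:
    def test_generation3_carriers_have_full_trails(self, clean_ds):
        """Without planted errors, any allele carried in the deepest
        generation must show parent and grandparent presence."""
        gen3 = [i for i in clean_ds.individuals if i.startswith("G3_")]
        g = clean_ds.genotypes
        carried = g[g["individual"].isin(gen3)]
        alleles = pd.concat([
            carried[["block_id", "allele1"]].rename(columns={"allele1": "code"}),
            carried[["block_id", "allele2"]].rename(columns={"allele2": "code"}),
        ]).drop_duplicates()
        presences = trace_alleles(alleles, g, clean_ds.ped)
        assert set(presences["segregation_class"]) <= {
            "parent_and_grandparent", "segregant"
        }

    def test_no_de_novo_calls_among_descendant_alleles(self, clean_ds):
        """Alleles carried by any non-founder are never classified de novo
        when no errors were planted."""
        founders = set(clean_ds.ped.founders())
        g = clean_ds.genotypes
        nonf = g[~g["individual"].isin(founders)]
        alleles = pd.concat([
            nonf[["block_id", "allele1"]].rename(columns={"allele1": "code"}),
            nonf[["block_id", "allele2"]].rename(columns={"allele2": "code"}),
        ]).drop_duplicates()
        presences = trace_alleles(alleles, g, clean_ds.ped)
        assert (presences["segregation_class"] != "de_novo").all()


class TestPlantedAdi:
    def test_nonheritable_adi_alleles_are_de_novo(self, adi_ds):
        """Random one-off calling errors have no ancestral trail."""
        events = pd.DataFrame(
            [{"block_id": e.block_id, "code": e.wrong}
             for e in adi_ds.ledger.adi_events]
        ).drop_duplicates()
        presences = trace_alleles(events, adi_ds.genotypes, adi_ds.ped)
        assert (presences["segregation_class"] == "de_novo").all()

    def test_heritable_adi_produces_grandparent_gaps(self, heritable_adi_ds):
        """Transmissible artifacts can express in a grandparent and a
        grandchild while skipping the parent."""
        ds = heritable_adi_ds
        events = pd.DataFrame(
            [{"block_id": e.block_id, "code": e.wrong}
             for e in ds.ledger.adi_events]
        ).drop_duplicates()
        presences = trace_alleles(events, ds.genotypes, ds.ped)
        classes = set(presences["segregation_class"])
        assert "grandparent_only" in classes


class TestVennTable:
    def test_all_de_novo(self):
        presences = trace_alleles(
            pd.DataFrame({"block_id": ["LB1"], "code": [106]}),
            _geno([("solo", "LB1", 106, 101)]),
            Pedigree([PedigreeRecord("solo")]),
        )
        cells = venn_table(presences)
        assert cells["none"] == 1
        assert sum(cells.values()) == 1

    def test_cells_sum_to_allele_count(self, adi_ds):
        events = pd.DataFrame(
            [{"block_id": e.block_id, "code": e.wrong}
             for e in adi_ds.ledger.adi_events]
        ).drop_duplicates()
        presences = trace_alleles(events, adi_ds.genotypes, adi_ds.ped)
        cells = venn_table(presences)
        assert sum(cells.values()) == len(presences)

    def test_segregant_lands_in_all_four_cell(self):
        ped = _three_gen_pedigree()
        rows = [("gpf", "LB1", 102, 101), ("gpm", "LB1", 101, 101),
                ("mate", "LB1", 102, 101), ("daughter", "LB1", 102, 101)]
        rows += [(f"son{k}", "LB1", 101, 102) for k in range(5)]
        # mate (father of sons) carries; gpf is maternal grandfather; to get
        # paternal grandparents, extend with mate's carrier father
        ped = Pedigree(
            [PedigreeRecord("pgf", sex="male"), PedigreeRecord("pgm", sex="female")]
            + [PedigreeRecord("gpf", sex="male"), PedigreeRecord("gpm", sex="female"),
               PedigreeRecord("mate", sire="pgf", dam="pgm", sex="male"),
               PedigreeRecord("daughter", sire="gpf", dam="gpm", sex="female")]
            + [PedigreeRecord(f"son{k}", sire="mate", dam="daughter", sex="male")
               for k in range(5)]
        )
        rows += [("pgf", "LB1", 102, 101), ("pgm", "LB1", 101, 101)]
        presences = trace_alleles(
            pd.DataFrame({"block_id": ["LB1"], "code": [102]}),
            _geno(rows), ped,
        )
        assert presences["segregation_class"].iloc[0] == "segregant"
        cells = venn_table(presences)
        assert cells["F+M+PGP+MGP"] == 1


class TestDotExport:
    def test_carriers_are_filled_nodes(self):
        ped = _three_gen_pedigree()
        lookup = GenotypeLookup(
            _geno([("daughter", "LB1", 102, 101), ("son0", "LB1", 102, 101)])
        )
        dot = carrier_pedigree_dot("LB1", 102, lookup, ped)
        assert dot.startswith("digraph")
        assert 'fillcolor=gray' in dot
        assert '"daughter" -> "son0"' in dot
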
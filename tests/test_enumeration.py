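"""Iterative enumeration: gates, frontier logic, provenance, determinism."""

import pytest

from focuslib.curation import standardize_record
from focuslib.enumeration import (
    EnumerationConfig,
    enumerate_library,
    expand_once,
    property_gate,
    replay_provenance,
)
from focuslib.rules import RuleCompendium

from conftest import record

GATES_OFF = EnumerationConfig(mw_max=1e9, tpsa_min=0.0, tpsa_max=1e9)


def subset(compendium, *ids) -> RuleCompendium:
    return RuleCompendium.from_rules([compendium[i] for i in ids], source="subset")


class TestPropertyGate:
    def test_mw_upper_bound_is_strict(self):
        # a molecule weighing exactly at the bound must fail
        from focuslib.molprops import compute_profile

        rec = record("CCO")
        mw = compute_profile(rec).MW
        at_bound = EnumerationConfig(mw_max=mw, tpsa_min=0.0, tpsa_max=200.0)
        assert property_gate(rec, at_bound) is False
        above = EnumerationConfig(mw_max=mw + 0.01, tpsa_min=0.0, tpsa_max=200.0)
        assert property_gate(rec, above) is True

    def test_tpsa_bounds_are_inclusive(self):
        from focuslib.molprops import compute_profile

        rec = record("C1COCCN1")  # morpholine
        tpsa = compute_profile(rec).TPSA
        at_lower = EnumerationConfig(tpsa_min=tpsa, tpsa_max=150.0)
        assert property_gate(rec, at_lower) is True
        at_upper = EnumerationConfig(tpsa_min=0.0, tpsa_max=tpsa)
        assert property_gate(rec, at_upper) is True

    def test_benzene_fails_default_tpsa_floor(self):
        assert property_gate(record("c1ccccc1"), EnumerationConfig()) is False

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            EnumerationConfig(tpsa_min=100.0, tpsa_max=50.0)
        with pytest.raises(ValueError):
            EnumerationConfig(n_iterations=-1)


class TestExpandOnce:
    def test_single_rule_single_product(self, compendium, toluene):
        products, _ = expand_once([toluene], subset(compendium, "R005"))
        assert len(products) == 1
        assert products[0].canonical_key == "CC1CCCCC1"
        assert products[0].provenance.rule_chain == ("R005",)
        assert products[0].provenance.seed_id == "toluene"

    def test_no_matches_is_empty(self, compendium, cyclohexane):
        products, _ = expand_once([cyclohexane], subset(compendium, "R005"))
        assert products == []

    def test_coinciding_products_keep_first_rules_provenance(self, compendium, toluene):
        # two copies of the phenyl->cyclohexyl rewrite under different ids
        first = compendium["R005"]
        import dataclasses

        clone = dataclasses.replace(first, rule_id="R905")
        forward = RuleCompendium.from_rules([first, clone])
        backward = RuleCompendium.from_rules(
            [dataclasses.replace(clone), dataclasses.replace(first)]
        )
        prod_fwd, _ = expand_once([toluene], forward)
        prod_bwd, _ = expand_once([toluene], backward)
        assert prod_fwd[0].provenance.rule_chain == ("R005",)
        assert prod_bwd[0].provenance.rule_chain == ("R905",)
        assert prod_fwd[0].canonical_key == prod_bwd[0].canonical_key


class TestEnumerateLibrary:
    def test_fixed_point_after_one_iteration(self, compendium, toluene):
        library = enumerate_library([toluene], subset(compendium, "R005"), GATES_OFF)
        assert len(library) == 1  # iteration 2 adds nothing: product has no phenyl
        assert library.records[0].provenance.iteration_born == 1

    def test_zero_iterations(self, compendium, toluene):
        config = EnumerationConfig(n_iterations=0)
        assert len(enumerate_library([toluene], compendium, config)) == 0
        with_seeds = EnumerationConfig(n_iterations=0, include_seeds_in_output=True)
        library = enumerate_library([toluene], compendium, with_seeds)
        assert [er.canonical_key for er in library.records] == [toluene.canonical_key]

    def test_empty_seed_set_is_an_error(self, compendium):
        with pytest.raises(ValueError):
            enumerate_library([], compendium)

    def test_symmetry_distinct_sites_bounded_by_site_count(self, compendium):
        # two symmetry-distinct phenyl rings -> at most 2 unique products
        seed = record("Cc1ccc(-c2ccccc2)cc1", "4-methylbiphenyl")
        library = enumerate_library(
            [seed], subset(compendium, "R005"),
            EnumerationConfig(n_iterations=1, mw_max=1e9, tpsa_min=0, tpsa_max=1e9),
        )
        assert len(library) == 2

    def test_monotone_in_iterations_and_antitone_in_gates(self, compendium, motif_seeds):
        comp = subset(compendium, "R005", "R003")
        sizes = [
            len(enumerate_library(motif_seeds, comp,
                                  EnumerationConfig(n_iterations=k, mw_max=1e9,
                                                    tpsa_min=0, tpsa_max=1e9)))
            for k in (0, 1, 2)
        ]
        assert sizes == sorted(sizes)
        loose = len(enumerate_library(motif_seeds, comp, GATES_OFF))
        tight = len(
            enumerate_library(motif_seeds, comp,
                              EnumerationConfig(mw_max=250.0, tpsa_min=40.0, tpsa_max=90.0))
        )
        assert tight <= loose

    def test_two_runs_are_byte_identical(self, compendium, motif_seeds):
        runs = [
            enumerate_library(motif_seeds, compendium).to_dataframe().to_csv(index=False)
            for _ in range(2)
        ]
        assert runs[0] == runs[1]

    def test_gate_soundness(self, compendium, motif_seeds):
        config = EnumerationConfig(mw_max=400.0, tpsa_min=40.0, tpsa_max=120.0)
        library = enumerate_library(motif_seeds, compendium, config)
        assert all(property_gate(er.record, config) for er in library.records)

    def test_provenance_replay_regenerates_every_record(self, compendium, motif_seeds):
        library = enumerate_library(motif_seeds, compendium)
        replay = replay_provenance(library, motif_seeds, compendium)
        assert replay and all(replay.values())

    def test_rule_chain_length_equals_iteration_born(self, compendium, motif_seeds):
        library = enumerate_library(motif_seeds, compendium)
        for er in library.records:
            assert len(er.provenance.rule_chain) == er.provenance.iteration_born >= 1

    def test_seeds_absent_unless_configured(self, compendium, toluene):
        library = enumerate_library([toluene], compendium, GATES_OFF)
        assert toluene.canonical_key not in {er.canonical_key for er in library.records}
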
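"""Rule engine: SMIRKS parsing, compendium handling, and rule application."""

import pytest
from rdkit import Chem

from focuslib.rules import (
    DuplicateIdError,
    InconsistentMappingError,
    InvalidInputError,
    MalformedSmirksError,
    SchemaError,
    TransformationType,
    apply_rule,
    load_compendium,
    parse_smirks,
    validate_compendium,
    write_compendium,
)

from conftest import record

PHENYL_TO_CYCLOHEXYL = (
    "[c;x2:2]1[c;x2:3][c;x2:4][c;x2:5][c;x2:6][c;x2:1]1"
    ">>[#6:5]-1-[#6:6]-[#6:1]-[#6:2]-[#6:3]-[#6:4]-1"
)


class TestParseSmirks:
    def test_compiles_phenyl_rewrite_with_six_mapped_atoms(self):
        compiled = parse_smirks(PHENYL_TO_CYCLOHEXYL)
        assert compiled.mapped_atoms == frozenset({1, 2, 3, 4, 5, 6})
        assert compiled.extension is None

    def test_missing_separator_is_malformed(self):
        with pytest.raises(MalformedSmirksError):
            parse_smirks("CCO")

    @pytest.mark.parametrize("bad", ["", "   ", ">>", "CC>>", ">>CC", "A>>B>>C"])
    def test_degenerate_strings_are_malformed(self, bad):
        with pytest.raises(MalformedSmirksError):
            parse_smirks(bad)

    def test_extension_block_is_stripped_and_recorded(self, compendium):
        carboxyl = compendium["R003"]
        compiled = parse_smirks(carboxyl.smirks)
        assert compiled.extension == "|s:0:1|"
        assert "|" not in compiled.smirks
        assert " " not in compiled.smirks

    def test_printed_whitespace_is_insignificant(self):
        spaced = PHENYL_TO_CYCLOHEXYL.replace("[c;x2:2]", "[c; x2:2]").replace(">>", " >> ")
        assert parse_smirks(spaced).smirks == parse_smirks(PHENYL_TO_CYCLOHEXYL).smirks

    def test_new_product_atoms_allowed_by_default_but_strict_raises(self, compendium):
        # the benzoylphenyl rule introduces an oxetane oxygen with a fresh map
        smirks = compendium["R004"].smirks
        compiled = parse_smirks(smirks)
        assert compiled.unmapped_product_maps
        with pytest.raises(InconsistentMappingError):
            parse_smirks(smirks, strict_mapping=True)


class TestCompendiumIO:
    def test_builtin_table_loads_all_printed_rules(self, compendium):
        assert len(compendium) == 7
        rule = compendium.get_by_name("Phenyl_to_cyclohexyl")
        assert rule.transformation_type is TransformationType.RING_SUBSTITUTION
        assert compendium.group_counts()["Phenyl"] == 3

    def test_header_only_file_gives_empty_compendium(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("rule_id\tgroup\tname\ttransformation_type\tsmirks\tnotes\treference\n")
        assert len(load_compendium(path)) == 0

    def test_missing_column_is_schema_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("rule_id\tgroup\tname\tsmirks\tnotes\treference\n")
        with pytest.raises(SchemaError):
            load_compendium(path)

    def test_duplicate_rule_id_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text(
            "rule_id,group,name,transformation_type,smirks,notes,reference\n"
            "R1,Phenyl,a,ring substitution,{s},,x\n"
            "R1,Phenyl,b,ring substitution,{s},,x\n".replace("{s}", PHENYL_TO_CYCLOHEXYL)
        )
        with pytest.raises(DuplicateIdError):
            load_compendium(path)

    def test_uncompilable_rows_kept_with_parse_error_status(self, tmp_path):
        path = tmp_path / "mixed.csv"
        path.write_text(
            "rule_id,group,name,transformation_type,smirks,notes,reference\n"
            f"R1,Phenyl,good,ring substitution,{PHENYL_TO_CYCLOHEXYL},,x\n"
            "R2,Phenyl,broken,other,not-a-smirks,,x\n"
        )
        comp = load_compendium(path)
        assert len(comp) == 2
        report = validate_compendium(comp, probes=[record("Cc1ccccc1")])
        assert report.statuses == {"R1": "parsed", "R2": "parse-error"}

    def test_round_trip_is_byte_identical(self, compendium, tmp_path):
        from focuslib.fixtures import builtin_rules_path

        out = tmp_path / "roundtrip.tsv"
        write_compendium(compendium, out)
        assert out.read_bytes() == builtin_rules_path().read_bytes()


class TestApplyRule:
    def test_toluene_to_methylcyclohexane(self, compendium, toluene):
        products = apply_rule(compendium["R005"], toluene)
        assert [p.canonical_key for p in products] == ["CC1CCCCC1"]

    def test_no_match_returns_empty_set(self, compendium, cyclohexane):
        assert apply_rule(compendium["R005"], cyclohexane) == []

    def test_symmetric_sites_collapse_under_dedup(self, compendium):
        biphenyl = record("c1ccc(-c2ccccc2)cc1")
        products = apply_rule(compendium["R005"], biphenyl)
        assert [p.canonical_key for p in products] == ["c1ccc(C2CCCCC2)cc1"]

    def test_carboxyl_rule_builds_ionized_thiazolidinedione(self, compendium):
        acetic = record("CC(=O)O")
        products = apply_rule(compendium["R003"], acetic)
        assert [p.canonical_key for p in products] == ["CC1SC(=O)[N-]C1=O"]

    def test_unsanitizable_input_raises(self, compendium):
        bad = Chem.MolFromSmiles("N(C)(C)(C)(C)C", sanitize=False)  # pentavalent N
        with pytest.raises(InvalidInputError):
            apply_rule(compendium["R005"], bad)

    def test_product_count_bounded_by_match_count(self, compendium, probes):
        for rule in compendium:
            query = rule.compiled.reactant_query
            for probe in [p for group in probes.values() for p in group]:
                n_matches = len(probe.structure.GetSubstructMatches(query, uniquify=False))
                assert len(apply_rule(rule, probe)) <= n_matches

    def test_dedup_idempotence(self, compendium, toluene):
        first = [p.canonical_key for p in apply_rule(compendium["R007"], toluene)]
        second = [p.canonical_key for p in apply_rule(compendium["R007"], toluene)]
        assert first == second


def _phenyl_to_cyclohexyl_oracle(mol: Chem.Mol) -> set[str]:
    """Exhaustive single-site rewrite of non-fused benzene rings by direct
    graph editing — independent of the reaction-application machinery."""
    pattern = Chem.MolFromSmarts("[c;x2]1[c;x2][c;x2][c;x2][c;x2][c;x2]1")
    out = set()
    for match in mol.GetSubstructMatches(pattern, uniquify=True):
        editable = Chem.RWMol(mol)
        for idx in match:
            atom = editable.GetAtomWithIdx(idx)
            atom.SetIsAromatic(False)
            atom.SetNoImplicit(False)
        for i in match:
            for j in match:
                bond = editable.GetBondBetweenAtoms(i, j)
                if bond is not None:
                    bond.SetBondType(Chem.BondType.SINGLE)
                    bond.SetIsAromatic(False)
        product = editable.GetMol()
        try:
            Chem.SanitizeMol(product)
        except Exception:
            continue
        flat = Chem.Mol(product)
        Chem.RemoveStereochemistry(flat)
        out.add(Chem.MolToSmiles(flat))
    return out


class TestOracleEquivalence:
    def test_matches_independent_graph_rewrite_on_all_probes(self, compendium, probes):
        """Reaction-based application equals exhaustive manual ring rewriting."""
        rule = compendium["R005"]
        checked = 0
        for probe in [p for group in probes.values() for p in group]:
            if probe.structure.GetNumHeavyAtoms() > 20:
                continue
            expected = _phenyl_to_cyclohexyl_oracle(probe.structure)
            expected.discard(probe.canonical_key)
            got = {p.canonical_key for p in apply_rule(rule, probe)}
            assert got == expected
            checked += 1
        assert checked >= 5


class TestValidateCompendium:
    def test_all_printed_rules_fire_on_their_motif_probes(self, compendium):
        report = validate_compendium(compendium)
        assert all(status == "parsed" for status in report.statuses.values())
        assert all(report.n_products[r] >= 1 for r in report.statuses)

    def test_statuses_partition_and_groups_sum_to_size(self, compendium):
        report = validate_compendium(compendium)
        assert set(report.statuses) == {rule.rule_id for rule in compendium}
        assert sum(report.status_counts.values()) == len(compendium)
        assert sum(report.group_counts.values()) == len(compendium)

    def test_probe_without_motif_reports_no_probe_match(self, compendium, cyclohexane):
        report = validate_compendium(compendium, probes=[cyclohexane])
        assert report.statuses["R005"] == "no-probe-match"
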
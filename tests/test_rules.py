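"""Rule engine: SMARTS compilation, weights, structural keys, validation."""

import random

import pytest
from rdkit import Chem

from chemtaxon.fixtures.seed_rules import THIAZOLE_SMARTS, build_seed_ruleset
from chemtaxon.rules import (
    ClassificationRule,
    RuleError,
    RuleSet,
    StructuralKey,
    compile_smarts,
    compute_structural_key,
    match_rule,
    parse_rule_file,
    rule_weight,
    validate_ruleset,
    write_rule_file,
)
from chemtaxon.standardize import preprocess
from conftest import permute_smiles


class TestCompileSmarts:
    def test_printed_thiazole_pattern_compiles(self):
        assert compile_smarts(THIAZOLE_SMARTS) is not None

    def test_benzene_compiles_truncated_fails(self):
        compile_smarts("c1ccccc1")
        with pytest.raises(RuleError, match="c1ccccc"):
            compile_smarts("c1ccccc")

    def test_every_seed_pattern_compiles(self, rs):
        for rule in rs.rules.values():
            for pattern in rule.patterns:
                assert compile_smarts(pattern) is not None


class TestMatchRule:
    def test_thiazole_superstructure_semantics(self, rs):
        thiazole = rs.rules["thiazoles"]
        assert match_rule(thiazole, preprocess("c1cscn1"))        # 1,3-thiazole
        assert match_rule(thiazole, preprocess("Cc1nccs1"))       # 2-methylthiazole
        assert not match_rule(thiazole, preprocess("c1ccsc1"))    # thiophene
        assert not match_rule(thiazole, preprocess("c1ocnc1"))    # oxazole

    def test_union_rule_not_directly_matchable(self, rs):
        with pytest.raises(RuleError, match="union categories"):
            match_rule(rs.rules["benzenoids"], preprocess("c1ccccc1"))

    def test_invariant_under_atom_reordering(self, rs):
        rng = random.Random(3)
        molecules = ["Cc1nccs1", "NCC(=O)NCC(O)=O", "Oc1ccccc1", "CC(C)O",
                     "OCC1OC(Oc2ccc3C(=O)C=C(Oc3c2)c2ccccc2)C(O)C(O)C1O"]
        for smiles in molecules:
            base = {
                rid: match_rule(rule, preprocess(smiles))
                for rid, rule in rs.rules.items()
                if rule.kind != "union"
            }
            for _ in range(5):
                shuffled = permute_smiles(smiles, rng)
                got = {
                    rid: match_rule(rule, preprocess(shuffled))
                    for rid, rule in rs.rules.items()
                    if rule.kind != "union"
                }
                assert got == base

    def test_stereo_rule_requires_stereo_annotated_input(self, rs):
        alpha = rs.rules["3-alpha-hydroxysteroids"]
        assert match_rule(alpha, preprocess("O[C@@H]1CCC2(C)C3CCC4(C)CCCC4C3CCC2C1"))
        assert not match_rule(alpha, preprocess("OC1CCC2(C)C3CCC4(C)CCCC4C3CCC2C1"))
        assert not match_rule(alpha, preprocess("O[C@H]1CCC2(C)C3CCC4(C)CCCC4C3CCC2C1"))


class TestRuleWeight:
    def test_thiazole_weight_is_ring_size(self, rs):
        assert rs.rules["thiazoles"].weight == 5

    def test_single_atom_pattern(self):
        rule = ClassificationRule("r", "CHEMONTID:0000001", "smarts", patterns=["[#6]"])
        assert rule_weight(rule) == 1

    def test_declared_predicate_weight(self, rs):
        assert rs.rules["alkanes"].weight == 3

    @pytest.mark.parametrize(
        ("pattern", "k"),
        [("c1ccc1", 4), ("c1cccc1", 5), ("c1ccccc1", 6), ("c1cccccc1", 7)],
    )
    def test_k_ring_pattern_weighs_k(self, pattern, k):
        rule = ClassificationRule("r", "CHEMONTID:0000001", "smarts", patterns=[pattern])
        assert rule_weight(rule) == k

    def test_multi_pattern_rule_takes_minimum(self):
        rule = ClassificationRule(
            "r", "CHEMONTID:0000001", "smarts", patterns=["c1ccccc1", "[#6][#6]"]
        )
        assert rule_weight(rule) == 2

    def test_no_seed_weight_exceeds_smallest_positive_example(self, rs):
        """Feature weights mirror the smallest compound satisfying the rule,
        so no weight may exceed its smallest positive example's heavy atoms."""
        for rule in rs.rules.values():
            if rule.kind == "union" or not rule.positive_examples:
                continue
            smallest = min(
                Chem.MolFromSmiles(smi).GetNumHeavyAtoms()
                for smi in rule.positive_examples
            )
            assert rule.weight <= smallest, rule.rule_id


class TestStructuralKey:
    def test_thiazole_key(self, rs):
        assert rs.rules["thiazoles"].structural_key == StructuralKey(
            cycles=1, heterocycles=1, ring_atoms=5, ring_heteroatoms=2,
            halogen_atoms=0, fused_rings=0, heteroatoms=2,
        )

    def test_single_carbon_key_all_zero(self):
        rule = ClassificationRule("r", "CHEMONTID:0000001", "smarts", patterns=["[#6]"])
        assert compute_structural_key(rule) == StructuralKey()

    def test_benzene_key(self):
        rule = ClassificationRule("r", "CHEMONTID:0000001", "smarts", patterns=["c1ccccc1"])
        assert compute_structural_key(rule) == StructuralKey(cycles=1, ring_atoms=6)

    def test_fused_ring_count(self):
        rule = ClassificationRule(
            "r", "CHEMONTID:0000001", "smarts", patterns=["c1ccc2ccccc2c1"]
        )
        key = compute_structural_key(rule)
        assert key.cycles == 2 and key.fused_rings == 2 and key.ring_atoms == 10

    def test_invariants_enforced(self):
        with pytest.raises(RuleError):
            StructuralKey(cycles=1, heterocycles=2)
        with pytest.raises(RuleError):
            StructuralKey(ring_atoms=1, ring_heteroatoms=2)


class TestParseRuleFile:
    def test_seed_file_parses_clean(self, tax):
        rs = parse_rule_file(build_seed_ruleset(), tax)
        assert len(rs.rules) >= 40
        assert rs.preferences

    def test_uncompilable_smarts_names_rule(self, tax):
        text = "rules:\n- id: broken\n  category: CHEMONTID:0000000\n  patterns: ['[#6((']\n"
        with pytest.raises(RuleError, match="broken"):
            parse_rule_file(text, tax)

    def test_predicate_without_weight_rejected(self, tax):
        text = (
            "rules:\n- id: alk\n  category: CHEMONTID:0000000\n  kind: predicate\n"
            "  expr: RingCount() = 0\n"
        )
        with pytest.raises(RuleError, match="weight"):
            parse_rule_file(text, tax)

    def test_unknown_category_rejected(self, tax):
        text = "rules:\n- id: r\n  category: CHEMONTID:7777777\n  patterns: ['[#6]']\n"
        with pytest.raises(RuleError, match="CHEMONTID:7777777"):
            parse_rule_file(text, tax)

    def test_round_trip_preserves_semantics(self, tax, rs):
        again = parse_rule_file(write_rule_file(rs), tax)
        assert set(again.rules) == set(rs.rules)
        for rid, rule in rs.rules.items():
            assert again.rules[rid].weight == rule.weight
            assert again.rules[rid].patterns == rule.patterns
        assert again.preferences == rs.preferences


class TestValidateRuleset:
    def test_seed_ruleset_clean(self, tax, rs):
        assert validate_ruleset(rs, tax) == []

    def test_positive_listed_as_negative_reported(self, tax):
        rule = ClassificationRule(
            "thiazole-bad", "CHEMONTID:0000001", "smarts",
            patterns=[THIAZOLE_SMARTS], negative_examples=["c1cscn1"],
        )
        issues = validate_ruleset(RuleSet({"thiazole-bad": rule}), tax)
        assert [i.code for i in issues] == ["negative-hit"]

    def test_dangling_category_reported(self, tax):
        rule = ClassificationRule("r", "CHEMONTID:7777777", "smarts", patterns=["[#6]"])
        issues = validate_ruleset(RuleSet({"r": rule}), tax)
        assert any(i.code == "dangling-category" for i in issues)

    def test_two_rules_per_category_rejected(self):
        a = ClassificationRule("a", "CHEMONTID:0000001", "smarts", patterns=["[#6]"])
        b = ClassificationRule("b", "CHEMONTID:0000001", "smarts", patterns=["[#7]"])
        with pytest.raises(RuleError, match="at most one"):
            RuleSet({"a": a, "b": b})
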
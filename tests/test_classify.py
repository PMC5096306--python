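"""Four-step pipeline: kingdom, features, reduction, direct parent, results."""

import random

import pytest

from chemtaxon.classify import (
    ClassificationError,
    assign_kingdom,
    classify,
    extract_features,
    molecular_framework,
    select_direct_parent,
)
from chemtaxon.rules import ClassificationRule, RuleSet, StructuralKey, match_rule
from chemtaxon.standardize import preprocess
from conftest import permute_smiles


def name(tax, cid):
    return tax.category(cid).name if cid else None


class TestKingdom:
    @pytest.mark.parametrize(
        ("smiles", "expected"),
        [
            ("C", "Organic compounds"),          # one carbon is enough
            ("CCO", "Organic compounds"),
            ("O", "Inorganic compounds"),        # no carbon
            ("O=C=O", "Inorganic compounds"),    # exception list
            ("[C-]#[O+]", "Inorganic compounds"),
            ("S=C=S", "Inorganic compounds"),
            ("C#N", "Inorganic compounds"),
            ("ClC#N", "Inorganic compounds"),    # non-hydrocarbyl cyanide derivative
            ("CC#N", "Organic compounds"),       # hydrocarbyl nitrile stays organic
        ],
    )
    def test_assignment(self, tax, smiles, expected):
        assert name(tax, assign_kingdom(preprocess(smiles), tax)) == expected

    def test_every_molecule_gets_exactly_one_kingdom(self, tax, golden):
        kingdoms = {name(tax, k) for k in tax.kingdoms()}
        for entry in golden:
            mol = preprocess(entry.smiles)
            if mol.is_mixture:
                continue
            assert name(tax, assign_kingdom(mol, tax)) in kingdoms


class TestExtractFeatures:
    def test_ethanol_matches_agree_with_per_rule_oracle(self, tax, rs):
        mol = preprocess("CCO")
        got = extract_features(mol, rs, tax)
        oracle = {
            rid for rid, rule in rs.rules.items()
            if rule.kind != "union" and rule.scope == "molecule"
            and match_rule(rule, mol)
        }
        assert oracle <= got
        assert {"alcohols", "primary-alcohols", "organooxygen"} <= got
        direct_names = {rs.rules[r].category_id for r in got}
        assert tax.find_by_name("Alcohols and polyols").id in direct_names

    def test_union_closure_adds_ancestor_category(self, tax, rs):
        mol = preprocess("O=C1C=C(Oc2ccccc21)c1ccccc1")  # a flavone
        got = extract_features(mol, rs, tax)
        assert "flavonoids" in got and "phenylpropanoids" in got

    def test_empty_ruleset_yields_empty_set(self, tax):
        assert extract_features(preprocess("CCO"), RuleSet(rules={}), tax) == set()


class TestSelectDirectParent:
    @pytest.fixture()
    def weighted_rules(self, tax):
        from chemtaxon.predicate import parse_predicate

        fg = tax.find_by_name("Flavonoid glycosides").id
        gly = tax.find_by_name("Glycosides").id
        always = parse_predicate("RingCount() >= 0")
        rules = {
            "fg": ClassificationRule("fg", fg, "predicate", expr=always, weight=21),
            "gly": ClassificationRule("gly", gly, "predicate", expr=always, weight=25),
        }
        return tax, fg, gly, rules

    def test_preference_pair_beats_larger_weight(self, weighted_rules):
        tax, fg, gly, rules = weighted_rules
        rs = RuleSet(rules=rules, preferences=[(fg, gly)])
        assert select_direct_parent({fg, gly}, rs, tax) == fg

    def test_without_preference_weight_wins(self, weighted_rules):
        tax, fg, gly, rules = weighted_rules
        rs = RuleSet(rules=rules)
        assert select_direct_parent({fg, gly}, rs, tax) == gly

    def test_single_candidate(self, tax, rs):
        thiazoles = tax.find_by_name("Thiazoles").id
        assert select_direct_parent({thiazoles}, rs, tax) == thiazoles

    def test_weight_tie_falls_back_to_structural_key(self, tax):
        a = tax.find_by_name("Thiazoles").id       # key: 1 heterocycle
        b = tax.find_by_name("Alkanes").id         # all-zero key
        from chemtaxon.predicate import parse_predicate
        rules = {
            "a": ClassificationRule("a", a, "predicate",
                                    expr=parse_predicate("RingCount() >= 0"), weight=5,
                                    structural_key=StructuralKey(cycles=1, heterocycles=1,
                                                                 ring_atoms=5, ring_heteroatoms=2,
                                                                 heteroatoms=2)),
            "b": ClassificationRule("b", b, "predicate",
                                    expr=parse_predicate("RingCount() >= 0"), weight=5),
        }
        assert select_direct_parent({a, b}, RuleSet(rules=rules), tax) == a

    def test_empty_candidates_unclassifiable(self, tax, rs):
        with pytest.raises(ClassificationError, match="unclassifiable"):
            select_direct_parent(set(), rs, tax)


class TestMolecularFramework:
    @pytest.mark.parametrize(
        ("smiles", "label"),
        [
            ("c1ccccc1", "aromatic homomonocyclic compound"),
            ("CCCCO", "aliphatic acyclic compound"),
            ("c1ccncc1", "aromatic heteromonocyclic compound"),
            ("C1CCCCC1", "aliphatic homomonocyclic compound"),
            ("C1CCOC1", "aliphatic heteromonocyclic compound"),
            ("c1ccc2ccccc2c1", "aromatic homopolycyclic compound"),
            ("OC1CCC2(C)C3CCC4(C)CCCC4C3CCC2C1", "aliphatic homopolycyclic compound"),
        ],
    )
    def test_labels(self, smiles, label):
        assert molecular_framework(preprocess(smiles)) == label

    def test_mixtures_have_no_framework(self):
        assert molecular_framework(preprocess("[Na+].[Cl-]")) is None


class TestGoldenCorpus:
    def test_corpus_is_large_enough(self, golden):
        assert len(golden) >= 50

    def test_every_entry_reproduced(self, tax, rs, golden):
        for entry in golden:
            result = classify(entry.smiles, "smiles", tax, rs)
            got = (
                name(tax, result.kingdom),
                name(tax, result.direct_parent),
                frozenset(name(tax, c) for c in result.alternative_parents),
                result.molecular_framework,
                result.shallow,
                result.is_mixture,
            )
            want = (
                entry.kingdom,
                entry.direct_parent,
                frozenset(entry.alternative_parents),
                entry.framework,
                entry.shallow,
                entry.mixture,
            )
            assert got == want, entry.rid

    def test_lineage_coherence_and_antichain(self, tax, rs, golden):
        for entry in golden:
            r = classify(entry.smiles, "smiles", tax, rs)
            chain = tax.ancestors(r.direct_parent) + [r.direct_parent]
            by_depth = {tax.depth(c): c for c in chain}
            assert r.kingdom == (by_depth.get(1) or r.direct_parent)
            assert r.superclass == by_depth.get(2)
            assert r.class_ == by_depth.get(3)
            assert r.subclass == by_depth.get(4)
            dp_depth = tax.depth(r.direct_parent)
            assert r.intermediate_nodes == [
                c for c in chain if 4 < tax.depth(c) < dp_depth
            ]
            members = set(r.alternative_parents) | {r.direct_parent}
            assert tax.reduce_to_antichain(members) == members

    def test_weight_dominance_absent_preferences(self, tax, rs, golden):
        preferred = {p for p, _ in rs.preferences}
        for entry in golden:
            r = classify(entry.smiles, "smiles", tax, rs)
            if r.shallow or r.direct_parent in preferred:
                continue
            dp_rule = rs.rule_for_category(r.direct_parent)
            for alt in r.alternative_parents:
                alt_rule = rs.rule_for_category(alt)
                if alt_rule is not None:
                    assert dp_rule.weight >= alt_rule.weight, entry.rid


class TestInvariance:
    def test_classification_invariant_under_atom_permutation(self, tax, rs, golden):
        rng = random.Random(17)
        eligible = [e for e in golden if not e.mixture][:20]
        assert len(eligible) == 20
        for entry in eligible:
            base = classify(entry.smiles, "smiles", tax, rs)
            for _ in range(20):
                shuffled = permute_smiles(entry.smiles, rng)
                again = classify(shuffled, "smiles", tax, rs)
                assert again.direct_parent == base.direct_parent, entry.rid
                assert again.alternative_parents == base.alternative_parents
                assert again.kingdom == base.kingdom
                assert again.molecular_framework == base.molecular_framework
                assert again.substituents == base.substituents

    def test_repeated_runs_identical(self, tax, rs):
        a = classify("NCC(=O)NCC(O)=O", "smiles", tax, rs)
        b = classify("NCC(=O)NCC(O)=O", "smiles", tax, rs)
        assert a == b


class TestMixtures:
    def test_organic_chlorine_salt(self, tax, rs):
        r = classify("C[NH3+].[Cl-]", "smiles", tax, rs)
        assert name(tax, r.kingdom) == "Organic compounds"
        assigned = {name(tax, c) for c in r.assigned_categories()}
        assert "Organic chlorine salts" in assigned
        assert "Inorganic compounds" not in assigned
        assert r.molecular_framework is None
        assert len(r.component_results) == 2

    def test_all_inorganic_mixture(self, tax, rs):
        r = classify("[Na+].[Cl-]", "smiles", tax, rs)
        assert name(tax, r.kingdom) == "Inorganic compounds"
        assert name(tax, r.direct_parent) == "Alkali metal salts"

    def test_shallow_fallback_is_kingdom_only(self, tax, rs):
        r = classify("O", "smiles", tax, rs)
        assert r.shallow
        assert r.direct_parent == r.kingdom
        assert r.alternative_parents == []

    def test_glycylglycine_direct_parent_is_dipeptides(self, tax, rs):
        r = classify("NCC(=O)NCC(O)=O", "smiles", tax, rs)
        assert name(tax, r.direct_parent) == "Dipeptides"
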
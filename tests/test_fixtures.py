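"""Seed artifacts and synthetic generators."""

from rdkit import Chem
from rdkit.Chem.rdMolDescriptors import CalcMolFormula, CalcNumRings

import pytest

from chemtaxon.classify import classify
from chemtaxon.fixtures.generators import (
    GeneratorConfig,
    gen_alkanes,
    gen_decorated,
)
from chemtaxon.fixtures.seed_rules import ALKANE_PREDICATE, THIAZOLE_SMARTS, build_seed_ruleset
from chemtaxon.fixtures.seed_taxonomy import build_seed_taxonomy
from chemtaxon.rules import match_rule
from chemtaxon.standardize import preprocess


class TestSeedTaxonomy:
    def test_size_and_shape(self, tax):
        assert 80 <= len(tax) <= 120
        assert len(tax.kingdoms()) == 2
        superclasses = {
            tax.category(c).name
            for k in tax.kingdoms()
            for c in tax.children(k)
        }
        assert {
            "Organoheterocyclic compounds", "Benzenoids",
            "Organic acids and derivatives", "Phenylpropanoids and polyketides",
            "Homogeneous metal compounds",
        } <= superclasses
        assert len(superclasses) >= 5

    def test_has_deep_branch(self, tax):
        assert tax.max_depth() >= 6

    def test_published_ids_reused(self, tax):
        assert tax.category("CHEMONTID:0003232").name == "3-alpha-hydroxysteroids"
        assert tax.category("CHEMONTID:0003027").name == "3-hydroxysteroids"
        assert tax.category("CHEMONTID:0002450").name == "Primary amines"

    def test_dioxane_reduction_pair_present(self, tax):
        dioxanes = tax.find_by_name("Dioxanes")
        d12 = tax.find_by_name("1,2-Dioxanes")
        assert d12.parent_id == dioxanes.id

    def test_obo_text_is_deterministic(self):
        assert build_seed_taxonomy() == build_seed_taxonomy()


class TestSeedRuleset:
    def test_at_least_forty_rules(self, rs):
        assert len(rs.rules) >= 40

    def test_thiazole_pattern_verbatim(self, rs):
        assert rs.rules["thiazoles"].patterns == [THIAZOLE_SMARTS]

    def test_alkane_rule_is_the_formula_conjunction(self, rs):
        expr = rs.rules["alkanes"].expr.unparse()
        for clause in ("RingCount() = 0", "AtomCount(C) > 0",
                       "(AtomCount(C) + AtomCount(H)) = TotalAtomCount()",
                       "AtomCount(H) = ((2 * AtomCount(C)) + 2)"):
            assert clause in expr
        assert ALKANE_PREDICATE.startswith("RingCount() = 0")

    def test_preference_pair_configured(self, tax, rs):
        names = {
            (tax.category(p).name, tax.category(s).name) for p, s in rs.preferences
        }
        assert ("Flavonoid glycosides", "Glycosides") in names

    def test_every_rule_has_examples_or_is_union(self, rs):
        for rule in rs.rules.values():
            if rule.kind != "union":
                assert rule.positive_examples, rule.rule_id

    def test_ruleset_text_is_deterministic(self):
        assert build_seed_ruleset() == build_seed_ruleset()


class TestGenerators:
    def test_alkanes_satisfy_formula(self):
        for smiles in gen_alkanes(GeneratorConfig(seed=9)):
            mol = Chem.MolFromSmiles(smiles)
            c = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 6)
            h = sum(a.GetTotalNumHs() for a in mol.GetAtoms())
            assert CalcNumRings(mol) == 0
            assert h == 2 * c + 2
            assert mol.GetNumAtoms() == c  # carbon-only tree

    def test_unbranched_range_classifies_as_alkanes(self, tax, rs):
        config = GeneratorConfig(min_carbons=1, max_carbons=8, count=0)
        smiles = gen_alkanes(config)
        assert smiles[:8] == ["C", "CC", "CCC", "CCCC", "CCCCC", "CCCCCC",
                              "CCCCCCC", "CCCCCCCC"]
        for s in smiles:
            r = classify(s, "smiles", tax, rs)
            lineage = {tax.category(c).name for c in r.assigned_categories()}
            assert "Alkanes" in lineage and "Saturated hydrocarbons" in lineage

    def test_generators_reproducible(self):
        config = GeneratorConfig(seed=123)
        assert gen_alkanes(config) == gen_alkanes(config)
        assert gen_decorated("pyridine", config=config) == \
            gen_decorated("pyridine", config=config)

    def test_isobutane_formula(self):
        assert CalcMolFormula(Chem.MolFromSmiles("CC(C)C")) == "C4H10"

    def test_decorated_thiazoles_keep_matching(self, rs):
        for smiles in gen_decorated("thiazole", ["methyl", "ethyl"]):
            assert match_rule(rs.rules["thiazoles"], preprocess(smiles)), smiles

    def test_zero_substituents_is_scaffold(self):
        assert gen_decorated("benzene", config=GeneratorConfig(count=1)) == ["c1ccccc1"]

    def test_unknown_scaffold_rejected(self):
        with pytest.raises(ValueError, match="unknown scaffold"):
            gen_decorated("porphyrin")

    def test_glucosylated_flavone_takes_preference_path(self, tax, rs):
        decorated = gen_decorated("flavone", ["glucosyl"], GeneratorConfig(count=3))
        glycosylated = [s for s in decorated if "OC9" in s]
        assert glycosylated
        for smiles in glycosylated:
            r = classify(smiles, "smiles", tax, rs)
            assert tax.category(r.direct_parent).name == "Flavonoid glycosides"
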
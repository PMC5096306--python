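"""Taxonomy model, OBO round-trip, and tree-algebra behavior."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chemtaxon.taxonomy import (
    Category,
    Taxonomy,
    TaxonomyError,
    parse_obo,
    validate_taxonomy,
    write_obo,
)

MINIMAL_OBO = """\
format-version: 1.2

[Term]
id: CHEMONTID:0000000
name: Chemical entities

[Term]
id: CHEMONTID:0000001
name: Organic compounds
is_a: CHEMONTID:0000000
"""


class TestParseObo:
    def test_minimal_tree(self):
        tax = parse_obo(MINIMAL_OBO)
        assert len(tax) == 2
        assert tax.depth("CHEMONTID:0000001") == 1
        assert tax.ancestors("CHEMONTID:0000001") == ["CHEMONTID:0000000"]

    def test_multiple_parents_rejected(self):
        text = MINIMAL_OBO + (
            "\n[Term]\nid: CHEMONTID:0000002\nname: X\n"
            "is_a: CHEMONTID:0000000\nis_a: CHEMONTID:0000001\n"
        )
        with pytest.raises(TaxonomyError, match="multiple parents violate tree"):
            parse_obo(text)

    def test_duplicate_id_rejected(self):
        text = MINIMAL_OBO + "\n[Term]\nid: CHEMONTID:0000001\nname: Dup\nis_a: CHEMONTID:0000000\n"
        with pytest.raises(TaxonomyError, match="CHEMONTID:0000001"):
            parse_obo(text)

    def test_dangling_is_a_rejected(self):
        text = MINIMAL_OBO + "\n[Term]\nid: CHEMONTID:0000002\nname: X\nis_a: CHEMONTID:9999998\n"
        with pytest.raises(TaxonomyError, match="undeclared"):
            parse_obo(text)

    def test_cycle_rejected(self):
        # two nodes pointing at each other (and no valid root among them)
        text = (
            "[Term]\nid: CHEMONTID:0000000\nname: root\n\n"
            "[Term]\nid: CHEMONTID:0000001\nname: A\nis_a: CHEMONTID:0000002\n\n"
            "[Term]\nid: CHEMONTID:0000002\nname: B\nis_a: CHEMONTID:0000001\n"
        )
        with pytest.raises(TaxonomyError, match="cycle"):
            parse_obo(text)

    def test_seed_root_has_two_kingdoms(self, tax):
        names = {tax.category(k).name for k in tax.kingdoms()}
        assert names == {"Organic compounds", "Inorganic compounds"}


class TestWriteObo:
    def test_round_trip_identity(self, tax):
        assert parse_obo(write_obo(tax)) == tax

    def test_round_trip_is_stable_bytes(self, tax):
        once = write_obo(tax)
        assert write_obo(parse_obo(once)) == once

    def test_single_root_taxonomy_single_stanza(self):
        tax = Taxonomy(
            {"CHEMONTID:0000000": Category("CHEMONTID:0000000", "root")},
            "CHEMONTID:0000000",
        )
        assert write_obo(tax).count("[Term]") == 1

    def test_thiazole_exact_synonym_survives(self, tax):
        text = write_obo(parse_obo(write_obo(tax)))
        stanzas = text.split("[Term]")
        thiazole = next(s for s in stanzas if "name: Thiazoles" in s)
        assert 'synonym: "1,3-thiazoles" EXACT []' in thiazole

    def test_terms_in_ascending_id_order(self, tax):
        text = write_obo(tax)
        ids = [line.split(": ")[1] for line in text.splitlines() if line.startswith("id: ")]
        assert ids == sorted(ids)


class TestTreeAlgebra:
    def test_ancestors_of_root_empty(self, tax):
        assert tax.ancestors(tax.root_id) == []

    def test_thiazole_ancestor_path(self, tax):
        thiazoles = tax.find_by_name("Thiazoles").id
        names = [tax.category(c).name for c in tax.ancestors(thiazoles)]
        assert names == [
            "Chemical entities",
            "Organic compounds",
            "Organoheterocyclic compounds",
            "Azoles",
        ]

    def test_depth_equals_ancestor_count_everywhere(self, tax):
        for cid in tax.categories:
            assert tax.depth(cid) == len(tax.ancestors(cid))

    def test_depth_conventions(self, tax):
        assert tax.depth(tax.root_id) == 0
        assert tax.depth(tax.find_by_name("Organic compounds").id) == 1
        assert tax.depth(tax.find_by_name("Benzenoids").id) == 2
        assert tax.depth(tax.find_by_name("Azoles").id) == 3
        assert tax.depth(tax.find_by_name("Thiazoles").id) == 4

    def test_unknown_id_raises(self, tax):
        with pytest.raises(TaxonomyError):
            tax.ancestors("CHEMONTID:9999990")

    def test_edge_count_is_nodes_minus_one(self, tax):
        edges = sum(1 for c in tax.categories.values() if c.parent_id is not None)
        assert edges == len(tax) - 1


class TestReduceToAntichain:
    def test_parent_child_keeps_child(self, tax):
        dioxanes = tax.find_by_name("Dioxanes").id
        d12 = tax.find_by_name("1,2-Dioxanes").id
        assert tax.reduce_to_antichain({dioxanes, d12}) == {d12}

    def test_antichain_unchanged_and_idempotent(self, tax):
        ids = {tax.find_by_name(n).id for n in ("Thiazoles", "Phenols", "Ketones")}
        reduced = tax.reduce_to_antichain(ids)
        assert reduced == ids
        assert tax.reduce_to_antichain(reduced) == reduced

    @given(st.data())
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_reduction_properties_hold_on_arbitrary_subsets(self, tax, data):
        ids = sorted(tax.categories)
        subset = set(data.draw(st.lists(st.sampled_from(ids), min_size=1, max_size=25)))
        reduced = tax.reduce_to_antichain(subset)
        assert reduced <= subset
        assert tax.reduce_to_antichain(reduced) == reduced
        for a in reduced:
            assert not any(a != b and tax.is_ancestor(a, b) for b in reduced)
        # every dropped member is an ancestor of something retained
        for dropped in subset - reduced:
            assert any(tax.is_ancestor(dropped, kept) for kept in subset)

    def test_matches_pairwise_oracle_on_random_subsets(self, tax):
        rng = random.Random(7)
        all_ids = sorted(tax.categories)
        for _ in range(120):
            subset = set(rng.sample(all_ids, 15))
            brute = {
                a for a in subset
                if not any(a != b and tax.is_ancestor(a, b) for b in subset)
            }
            assert tax.reduce_to_antichain(subset) == brute


class TestValidateTaxonomy:
    def test_seed_taxonomy_clean(self, tax):
        assert validate_taxonomy(tax) == []

    def test_depth_bound_violation(self):
        cats = {"CHEMONTID:0000000": Category("CHEMONTID:0000000", "root")}
        prev = "CHEMONTID:0000000"
        for i in range(1, 13):
            cid = f"CHEMONTID:{i:07d}"
            cats[cid] = Category(cid, f"n{i}", parent_id=prev)
            prev = cid
        tax = Taxonomy(cats, "CHEMONTID:0000000")
        codes = {issue.code for issue in validate_taxonomy(tax)}
        assert "depth" in codes

    def test_malformed_id_rejected_at_construction(self):
        with pytest.raises(TaxonomyError, match="CHEMONTID"):
            Category("CHEM:1", "bad")

    def test_root_without_two_kingdoms_flagged(self):
        cats = {
            "CHEMONTID:0000000": Category("CHEMONTID:0000000", "root"),
            "CHEMONTID:0000001": Category(
                "CHEMONTID:0000001", "only", parent_id="CHEMONTID:0000000"
            ),
        }
        tax = Taxonomy(cats, "CHEMONTID:0000000")
        codes = {issue.code for issue in validate_taxonomy(tax)}
        assert "kingdoms" in codes
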
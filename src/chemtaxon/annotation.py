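"""Human-readable outputs: description text, substituents, external xrefs.

Description sentences are rendered from data-driven templates (shipped in
``data/templates.yaml``) so the wording can evolve without touching code.
A missing piece (no framework, no substituents) simply omits its sentence —
templates never render empty slots.
"""

from __future__ import annotations

from importlib import resources
from typing import TYPE_CHECKING

import yaml

from .taxonomy import Taxonomy

if TYPE_CHECKING:  # avoid a circular import at runtime
    from .classify import ClassificationResult
    from .rules import RuleSet

__all__ = ["external_descriptors", "generate_description", "list_substituents"]

_TEMPLATES: dict | None = None


def _templates() -> dict:
    global _TEMPLATES
    if _TEMPLATES is None:
        text = (
            resources.files("chemtaxon").joinpath("data/templates.yaml").read_text()
        )
        _TEMPLATES = yaml.safe_load(text)
    return _TEMPLATES


def _lower_first(text: str) -> str:
    return text[0].lower() + text[1:] if text else text


def generate_description(result: "ClassificationResult", tax: Taxonomy) -> str:
    """Deterministic 20–80 word description from the direct parent's name
    and definition, the molecular framework, and the substituent list."""
    t = _templates()
    parent = tax.category(result.direct_parent)
    sentences: list[str] = []
    compound = result.input_string if len(result.input_string) <= 60 else result.smiles
    sentences.append(
        t["membership"].format(
            compound=compound, parent=_lower_first(parent.name)
        )
    )
    if parent.definition:
        definition = parent.definition.rstrip(".")
        sentences.append(t["definition"].format(definition=definition))
    if result.molecular_framework:
        sentences.append(t["framework"].format(framework=result.molecular_framework))
    if result.substituents:
        shown = result.substituents[:8]
        sentences.append(t["substituents"].format(substituents=", ".join(shown)))
    return " ".join(sentences)


def list_substituents(matched_rules: set[str], rs: "RuleSet") -> list[str]:
    """Alphabetical, deduplicated display names of matched substituent rules;
    independent of rule evaluation order."""
    names = {
        rule.substituent_name or rs.rules[rid].category_id
        for rid, rule in ((rid, rs.rules[rid]) for rid in matched_rules if rid in rs.rules)
        if rule.is_substituent
    }
    return sorted(names)


def external_descriptors(
    result: "ClassificationResult", tax: Taxonomy
) -> list[tuple[str, str, str]]:
    """(source, foreign id, category id) for every assigned category's xrefs,
    grouped by source, deduplicated across the lineage."""
    out: list[tuple[str, str, str]] = []
    seen: set[tuple[str, str]] = set()
    for cid in result.assigned_categories():
        if cid not in tax:
            continue
        for xref in tax.category(cid).xrefs:
            pair = (xref.source, xref.foreign_id)
            if pair not in seen:
                seen.add(pair)
                out.append((xref.source, xref.foreign_id, cid))
    out.sort(key=lambda t: (t[0], t[1]))
    return out
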
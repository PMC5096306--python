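"""The four-step classification pipeline.

1. *Preprocessing* — parse, normalize, aromatize, split into components
   (:mod:`chemtaxon.standardize`).
2. *Feature extraction* — evaluate every structural rule against the
   molecule (superstructure search for SMARTS rules, whole-molecule
   evaluation for predicate rules), then close over union categories.
3. *Category assignment and reduction* — map matched rules to taxonomy
   categories and reduce the set to an antichain: whenever an assigned
   category is an ancestor of another assigned category, only the more
   specific one is kept.
4. *Direct-parent selection* — among the surviving candidates, pick the one
   whose rule has the largest feature weight; ties fall back to the
   structural key (field by field, larger wins) and finally to ascending
   category id.  Configured preference pairs override pure size: when both
   members of a pair are candidates, the suppressed one is removed before
   weighing (e.g. "flavonoid glycosides" beats the often-larger
   "glycosides").

The kingdom (organic vs. inorganic) is decided by carbon content with a
configurable exception list (carbon oxides/sulfides, cyanides and their
non-hydrocarbyl derivatives are inorganic despite containing carbon).
Multi-component inputs are classified per component and as a whole; a
mixture with any organic component is rooted in the organic kingdom and
inorganic-only categories are excluded from its merged result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdkit import Chem

from . import annotation
from .rules import ClassificationRule, RuleSet, match_rule
from .standardize import StandardizedMolecule, preprocess
from .taxonomy import Taxonomy

__all__ = [
    "ClassificationError",
    "ClassificationResult",
    "ClassifierConfig",
    "assign_kingdom",
    "classify",
    "classify_mixture",
    "extract_features",
    "molecular_framework",
    "select_direct_parent",
]


class ClassificationError(ValueError):
    pass


@dataclass(frozen=True)
class ClassifierConfig:
    """Kingdom names and the inorganic exception list.

    ``inorganic_exception_smiles`` are exact structures (compared on
    canonical SMILES); ``inorganic_exception_smarts`` catch derivative
    families such as non-hydrocarbyl cyanides.
    """

    organic_kingdom_name: str = "Organic compounds"
    inorganic_kingdom_name: str = "Inorganic compounds"
    inorganic_exception_smiles: tuple[str, ...] = (
        "[C-]#[O+]",  # carbon monoxide
        "O=C=O",      # carbon dioxide
        "[C]=S",      # carbon monosulfide
        "S=C=S",      # carbon disulfide
        "C#N",        # hydrogen cyanide
        "[C-]#N",     # cyanide anion
    )
    inorganic_exception_smarts: tuple[str, ...] = (
        "[!#6;!#1][CX2]#[NX1]",   # cyanide on a non-carbon atom
        "[!#6;!#1][NX2]=[CX2]",   # isocyanide-derived, non-hydrocarbyl
    )


DEFAULT_CONFIG = ClassifierConfig()


@dataclass
class ClassificationResult:
    """Kingdom-to-direct-parent lineage plus the annotation payload.

    All category references are ids; ``category_names`` carries the id→name
    mapping for every referenced category so results serialize standalone.
    """

    input_string: str
    smiles: str
    kingdom: str
    direct_parent: str
    superclass: str | None = None
    class_: str | None = None
    subclass: str | None = None
    intermediate_nodes: list[str] = field(default_factory=list)
    alternative_parents: list[str] = field(default_factory=list)
    substituents: list[str] = field(default_factory=list)
    molecular_framework: str | None = None
    description: str = ""
    external_descriptors: list[tuple[str, str, str]] = field(default_factory=list)
    matched_rules: list[str] = field(default_factory=list)
    shallow: bool = False
    is_mixture: bool = False
    component_results: list["ClassificationResult"] = field(default_factory=list)
    category_names: dict[str, str] = field(default_factory=dict)

    def assigned_categories(self) -> list[str]:
        """Direct parent, its lineage, and the alternative parents."""
        seen: list[str] = []
        for cid in (
            [self.kingdom, self.superclass, self.class_, self.subclass]
            + self.intermediate_nodes
            + [self.direct_parent]
            + self.alternative_parents
        ):
            if cid is not None and cid not in seen:
                seen.append(cid)
        return seen


# -- kingdom -------------------------------------------------------------------


def _is_inorganic_exception(mol: StandardizedMolecule, config: ClassifierConfig) -> bool:
    canon = {
        Chem.MolToSmiles(Chem.MolFromSmiles(s)) for s in config.inorganic_exception_smiles
    }
    if mol.canonical_smiles in canon:
        return True
    for smarts in config.inorganic_exception_smarts:
        patt = Chem.MolFromSmarts(smarts)
        if patt is not None and mol.mol.HasSubstructMatch(patt):
            return True
    return False


def assign_kingdom(
    mol: StandardizedMolecule,
    tax: Taxonomy,
    config: ClassifierConfig = DEFAULT_CONFIG,
) -> str:
    """Organic iff the structure contains carbon and is not a configured
    inorganic exception (carbon oxides/sulfides, cyanide-like species)."""
    organic = tax.find_by_name(config.organic_kingdom_name).id
    inorganic = tax.find_by_name(config.inorganic_kingdom_name).id
    if mol.carbon_count >= 1 and not _is_inorganic_exception(mol, config):
        return organic
    return inorganic


# -- feature extraction --------------------------------------------------------


def extract_features(
    mol: StandardizedMolecule,
    rs: RuleSet,
    tax: Taxonomy | None = None,
    include_mixture_rules: bool = False,
) -> set[str]:
    """Matched rule ids for one entity; deterministic.

    Molecule-scope SMARTS and predicate rules are evaluated directly; a
    union rule is added when any matched rule's category descends from the
    union's category (requires ``tax``).  Mixture-scope rules are skipped
    unless requested (the mixture path evaluates them on the whole entity).
    """
    matched: set[str] = set()
    for rule in rs.matchable_rules():
        if rule.scope == "mixture" and not include_mixture_rules:
            continue
        if match_rule(rule, mol):
            matched.add(rule.rule_id)
    if tax is not None:
        matched_categories = {rs.rules[rid].category_id for rid in matched}
        for union in rs.union_rules():
            if union.category_id not in tax:
                continue
            if any(
                cid in tax and tax.is_ancestor(union.category_id, cid)
                for cid in matched_categories
            ):
                matched.add(union.rule_id)
    return matched


# -- direct parent -------------------------------------------------------------


def select_direct_parent(
    candidates: set[str] | frozenset[str],
    rs: RuleSet,
    tax: Taxonomy,
) -> str:
    """Largest-feature selection with structural-key and id tie-breaks."""
    pool = set(candidates)
    if not pool:
        raise ClassificationError("unclassifiable: empty candidate set")
    for preferred, suppressed in rs.preferences:
        if preferred in pool and suppressed in pool:
            pool.discard(suppressed)

    def sort_key(cid: str):
        rule = rs.rule_for_category(cid)
        if rule is None:
            raise ClassificationError(f"candidate {cid} has no rule")
        return (-rule.weight, tuple(-v for v in rule.structural_key.as_tuple()), cid)

    return min(pool, key=sort_key)


# -- molecular framework -------------------------------------------------------


def molecular_framework(mol: StandardizedMolecule) -> str | None:
    """Coarse aromaticity × ring-topology descriptor; None for mixtures."""
    if mol.is_mixture:
        return None
    if mol.ring_count == 0:
        return "aliphatic acyclic compound"
    aromatic = "aromatic" if mol.aromatic_ring_count >= 1 else "aliphatic"
    ring_heteroatoms = sum(
        1
        for atom in mol.mol.GetAtoms()
        if atom.IsInRing() and atom.GetAtomicNum() not in (1, 6)
    )
    hetero = "hetero" if ring_heteroatoms >= 1 else "homo"
    cyclicity = "monocyclic" if mol.ring_count == 1 else "polycyclic"
    return f"{aromatic} {hetero}{cyclicity} compound"


# -- assembly ------------------------------------------------------------------


def _lineage_slots(tax: Taxonomy, direct_parent: str) -> tuple[
    str | None, str | None, str | None, list[str]
]:
    chain = tax.ancestors(direct_parent) + [direct_parent]
    by_depth = {tax.depth(cid): cid for cid in chain}

    def slot(d: int) -> str | None:
        return by_depth.get(d)

    dp_depth = tax.depth(direct_parent)
    intermediates = [
        cid for cid in chain if 4 < tax.depth(cid) < dp_depth
    ]
    return slot(2), slot(3), slot(4), intermediates


def _build_result(
    *,
    input_string: str,
    sm: StandardizedMolecule,
    kingdom: str,
    matched_rule_ids: set[str],
    candidate_categories: set[str],
    tax: Taxonomy,
    rs: RuleSet,
    is_mixture: bool,
    component_results: list[ClassificationResult] | None = None,
) -> ClassificationResult:
    reduced = tax.reduce_to_antichain(candidate_categories)
    shallow = not reduced
    if shallow:
        direct_parent = kingdom
        alternatives: list[str] = []
    else:
        direct_parent = select_direct_parent(reduced, rs, tax)
        def alt_key(cid: str):
            rule = rs.rule_for_category(cid)
            return (-(rule.weight if rule else 0), cid)
        alternatives = sorted((c for c in reduced if c != direct_parent), key=alt_key)
    superclass, class_, subclass, intermediates = _lineage_slots(tax, direct_parent)
    result = ClassificationResult(
        input_string=input_string,
        smiles=sm.canonical_smiles,
        kingdom=kingdom,
        direct_parent=direct_parent,
        superclass=superclass,
        class_=class_,
        subclass=subclass,
        intermediate_nodes=intermediates,
        alternative_parents=alternatives,
        molecular_framework=molecular_framework(sm),
        matched_rules=sorted(matched_rule_ids),
        shallow=shallow,
        is_mixture=is_mixture,
        component_results=component_results or [],
    )
    result.substituents = annotation.list_substituents(matched_rule_ids, rs)
    result.external_descriptors = annotation.external_descriptors(result, tax)
    result.category_names = {
        cid: tax.category(cid).name for cid in result.assigned_categories()
    }
    result.description = annotation.generate_description(result, tax)
    return result


def _classify_single(
    input_string: str,
    sm: StandardizedMolecule,
    tax: Taxonomy,
    rs: RuleSet,
    config: ClassifierConfig,
) -> ClassificationResult:
    kingdom = assign_kingdom(sm, tax, config)
    matched = extract_features(sm, rs, tax)
    categories = {
        rs.rules[rid].category_id for rid in matched if rs.rules[rid].category_id in tax
    }
    # keep only categories under the assigned kingdom
    categories = {cid for cid in categories if tax.kingdom_of(cid) == kingdom}
    return _build_result(
        input_string=input_string,
        sm=sm,
        kingdom=kingdom,
        matched_rule_ids=matched,
        candidate_categories=categories,
        tax=tax,
        rs=rs,
        is_mixture=False,
    )


def classify_mixture(
    sm: StandardizedMolecule,
    tax: Taxonomy,
    rs: RuleSet,
    config: ClassifierConfig = DEFAULT_CONFIG,
    input_string: str | None = None,
) -> ClassificationResult:
    """Classify a multi-component entity: each organic moiety separately and
    the entity as a whole (mixture-scope rules see all components)."""
    if not sm.is_mixture:
        raise ClassificationError("classify_mixture requires >= 2 components")
    organic = tax.find_by_name(config.organic_kingdom_name).id
    component_results = [
        _classify_single(comp.canonical_smiles, comp, tax, rs, config)
        for comp in sm.components
    ]
    kingdom = organic if any(r.kingdom == organic for r in component_results) else \
        tax.find_by_name(config.inorganic_kingdom_name).id
    matched: set[str] = set()
    for res in component_results:
        matched.update(res.matched_rules)
    for rule in rs.matchable_rules():
        if rule.scope == "mixture" and match_rule(rule, sm):
            matched.add(rule.rule_id)
    matched_categories = {
        rs.rules[rid].category_id for rid in matched if rs.rules[rid].category_id in tax
    }
    for union in rs.union_rules():
        if union.category_id in tax and any(
            cid in tax and tax.is_ancestor(union.category_id, cid)
            for cid in matched_categories
        ):
            matched.add(union.rule_id)
            matched_categories.add(union.category_id)
    candidates = {cid for cid in matched_categories if tax.kingdom_of(cid) == kingdom}
    return _build_result(
        input_string=input_string if input_string is not None else sm.canonical_smiles,
        sm=sm,
        kingdom=kingdom,
        matched_rule_ids=matched,
        candidate_categories=candidates,
        tax=tax,
        rs=rs,
        is_mixture=True,
        component_results=component_results,
    )


def classify(
    input_string: str,
    fmt: str,
    tax: Taxonomy,
    rs: RuleSet,
    config: ClassifierConfig = DEFAULT_CONFIG,
) -> ClassificationResult:
    """End-to-end classification of one input record (pure function of its
    arguments; byte-stable across runs and input atom orderings)."""
    sm = preprocess(input_string, fmt)
    if sm.is_mixture:
        return classify_mixture(sm, tax, rs, config, input_string=input_string)
    return _classify_single(input_string, sm, tax, rs, config)
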
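"""Classification rules: SMARTS patterns, formula predicates, and unions.

A rule binds one taxonomy category to matching logic plus a *feature
weight* — the number of non-hydrogen atoms of the substructure the rule
describes.  For SMARTS rules the weight is computed from the pattern (the
minimum over alternatives); for predicate rules, where no single pattern
exists, the weight is declared in the rule file as the heavy-atom count of
the smallest compound satisfying the constraints.  Weights drive direct-
parent selection: the biggest recognized feature wins.

Each rule also carries a seven-count *structural key* (cycles, heterocycles,
ring atoms, ring heteroatoms, halogen atoms, fused rings, heteroatoms) used
to break weight ties, plus positive/negative example structures used by
:func:`validate_ruleset`.

Union rules carry no matching logic of their own: a union category (e.g.
"Phenylpropanoids and polyketides") is assigned exactly when one of its
descendant categories is assigned.

Matching is superstructure search: the library pattern must embed in the
(usually larger) query molecule.  Patterns are matched against the
aromatized standardized form and, failing that, against a kekulized copy, so
patterns written with explicit alternating bonds (a common way to draw
heteroaromatic rings) still hit aromatized queries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml
from rdkit import Chem

from .predicate import PredicateError, PredicateExpr, parse_predicate
from .standardize import StandardizedMolecule, preprocess
from .taxonomy import Taxonomy

__all__ = [
    "ClassificationRule",
    "RuleError",
    "RuleSet",
    "StructuralKey",
    "compile_smarts",
    "compute_structural_key",
    "match_rule",
    "parse_rule_file",
    "rule_weight",
    "validate_ruleset",
    "write_rule_file",
]

RULE_KINDS = ("smarts", "predicate", "union")
_HALOGENS = {9, 17, 35, 53, 85}


class RuleError(ValueError):
    """Malformed rule definitions or misuse of a rule."""


@dataclass(frozen=True)
class StructuralKey:
    """Tie-break vector; fields listed in comparison order, larger wins."""

    cycles: int = 0
    heterocycles: int = 0
    ring_atoms: int = 0
    ring_heteroatoms: int = 0
    halogen_atoms: int = 0
    fused_rings: int = 0
    heteroatoms: int = 0

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) < 0:
                raise RuleError(f"structural key field {name} must be >= 0")
        if self.ring_heteroatoms > self.ring_atoms:
            raise RuleError("ring_heteroatoms cannot exceed ring_atoms")
        if self.heterocycles > self.cycles:
            raise RuleError("heterocycles cannot exceed cycles")

    def as_tuple(self) -> tuple[int, ...]:
        return (
            self.cycles,
            self.heterocycles,
            self.ring_atoms,
            self.ring_heteroatoms,
            self.halogen_atoms,
            self.fused_rings,
            self.heteroatoms,
        )


# -- SMARTS helpers ------------------------------------------------------------


def compile_smarts(pattern: str) -> Chem.Mol:
    """Compile a SMARTS pattern into a matcher; raises on parse failure."""
    mol = Chem.MolFromSmarts(pattern)
    if mol is None:
        raise RuleError(f"uncompilable SMARTS pattern: {pattern!r}")
    return mol


def _recursive_alternatives(pattern: str) -> list[str] | None:
    """If ``pattern`` is a single atom of the form ``[$(...),$(...),...]``,
    return the inner alternatives, else None."""
    p = pattern.strip()
    if not (p.startswith("[") and p.endswith("]")):
        return None
    body = p[1:-1]
    parts: list[str] = []
    depth = 0
    cur = ""
    for ch in body:
        if ch == "," and depth == 0:
            parts.append(cur)
            cur = ""
        else:
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
            cur += ch
    parts.append(cur)
    inner: list[str] = []
    for part in parts:
        part = part.strip()
        if not (part.startswith("$(") and part.endswith(")")):
            return None
        inner.append(part[2:-1])
    return inner


def _pattern_heavy_atom_count(pattern: str) -> int:
    alts = _recursive_alternatives(pattern)
    if alts:
        return min(_pattern_heavy_atom_count(a) for a in alts)
    mol = compile_smarts(pattern)
    return sum(1 for atom in mol.GetAtoms() if atom.GetAtomicNum() != 1)


def _minimal_pattern(patterns: list[str]) -> str:
    """The pattern (descending into recursive alternatives) with the fewest
    heavy atoms; ties go to file order."""
    best = min(patterns, key=_pattern_heavy_atom_count)
    alts = _recursive_alternatives(best)
    if alts:
        return _minimal_pattern(alts)
    return best


def _key_from_pattern(pattern: str) -> StructuralKey:
    mol = compile_smarts(pattern)
    mol.UpdatePropertyCache(strict=False)
    Chem.FastFindRings(mol)
    info = mol.GetRingInfo()
    atom_rings = info.AtomRings()
    bond_rings = info.BondRings()
    ring_atom_idx = {i for ring in atom_rings for i in ring}

    def is_hetero(idx: int) -> bool:
        return mol.GetAtomWithIdx(idx).GetAtomicNum() not in (0, 1, 6)

    fused = sum(
        1
        for i, ring in enumerate(bond_rings)
        if any(set(ring) & set(other) for j, other in enumerate(bond_rings) if j != i)
    )
    return StructuralKey(
        cycles=len(atom_rings),
        heterocycles=sum(1 for ring in atom_rings if any(is_hetero(i) for i in ring)),
        ring_atoms=len(ring_atom_idx),
        ring_heteroatoms=sum(1 for i in ring_atom_idx if is_hetero(i)),
        halogen_atoms=sum(
            1 for atom in mol.GetAtoms() if atom.GetAtomicNum() in _HALOGENS
        ),
        fused_rings=fused,
        heteroatoms=sum(1 for atom in mol.GetAtoms() if atom.GetAtomicNum() not in (0, 1, 6)),
    )


# -- rule ----------------------------------------------------------------------


@dataclass
class ClassificationRule:
    rule_id: str
    category_id: str
    kind: str
    patterns: list[str] = field(default_factory=list)
    expr: PredicateExpr | None = None
    weight: int = 0
    structural_key: StructuralKey = field(default_factory=StructuralKey)
    is_substituent: bool = False
    substituent_name: str | None = None
    stereo_specific: bool = False
    scope: str = "molecule"  # "mixture" rules fire only on multi-component input
    positive_examples: list[str] = field(default_factory=list)
    negative_examples: list[str] = field(default_factory=list)
    _compiled: list[Chem.Mol] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if self.kind not in RULE_KINDS:
            raise RuleError(f"rule {self.rule_id}: unknown kind {self.kind!r}")
        if self.kind == "smarts":
            if not self.patterns:
                raise RuleError(f"rule {self.rule_id}: smarts rule without patterns")
            for pat in self.patterns:
                try:
                    self._compiled.append(compile_smarts(pat))
                except RuleError as exc:
                    raise RuleError(f"rule {self.rule_id}: {exc}") from None
        elif self.kind == "predicate":
            if self.expr is None:
                raise RuleError(f"rule {self.rule_id}: predicate rule without expr")
            if self.weight < 1:
                raise RuleError(
                    f"rule {self.rule_id}: predicate rule must declare a weight >= 1"
                )
        else:  # union
            if self.patterns or self.expr is not None:
                raise RuleError(
                    f"rule {self.rule_id}: union rules carry no patterns or expr"
                )
            if self.weight < 1:
                self.weight = 1


def rule_weight(rule: ClassificationRule) -> int:
    """Non-hydrogen atom count semantics (see module docstring)."""
    if rule.kind == "smarts":
        return min(_pattern_heavy_atom_count(p) for p in rule.patterns)
    return rule.weight


def compute_structural_key(rule: ClassificationRule) -> StructuralKey:
    """Seven ring/heteroatom counts from the rule's minimal pattern; declared
    (default all-zero) for predicate and union rules."""
    if rule.kind == "smarts":
        return _key_from_pattern(_minimal_pattern(rule.patterns))
    return rule.structural_key


def match_rule(rule: ClassificationRule, mol: StandardizedMolecule) -> bool:
    """Superstructure test; deterministic and atom-order independent."""
    if rule.kind == "union":
        raise RuleError("union categories are not directly matchable")
    if rule.kind == "predicate":
        assert rule.expr is not None
        return rule.expr.evaluate(mol)
    use_chirality = rule.stereo_specific
    for query in rule._compiled:
        if mol.mol.HasSubstructMatch(query, useChirality=use_chirality):
            return True
        try:
            kek = mol.kekulized()
        except Chem.KekulizeException:  # pragma: no cover - defensive
            continue
        if kek.HasSubstructMatch(query, useChirality=use_chirality):
            return True
    return False


# -- rule set ------------------------------------------------------------------


@dataclass
class RuleSet:
    rules: dict[str, ClassificationRule]
    preferences: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        by_category: dict[str, str] = {}
        for rule in self.rules.values():
            if rule.kind != "union":
                prev = by_category.get(rule.category_id)
                if prev is not None:
                    raise RuleError(
                        f"categories may carry at most one non-union rule: "
                        f"{rule.category_id} has {prev} and {rule.rule_id}"
                    )
                by_category[rule.category_id] = rule.rule_id
        for preferred, suppressed in self.preferences:
            if preferred == suppressed:
                raise RuleError("preference pair must reference distinct categories")

    def rule_for_category(self, category_id: str) -> ClassificationRule | None:
        for rule in self.rules.values():
            if rule.category_id == category_id:
                return rule
        return None

    def matchable_rules(self) -> list[ClassificationRule]:
        return [r for r in self.rules.values() if r.kind != "union"]

    def union_rules(self) -> list[ClassificationRule]:
        return [r for r in self.rules.values() if r.kind == "union"]


def parse_rule_file(text: str, tax: Taxonomy | None = None) -> RuleSet:
    """Parse the YAML rule format into a compiled, weighted :class:`RuleSet`.

    Every SMARTS pattern is compiled eagerly; predicate rules must declare a
    weight; with a taxonomy supplied, category references are checked.
    """
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise RuleError(f"rule file is not valid YAML: {exc}") from None
    if not isinstance(doc, dict) or "rules" not in doc:
        raise RuleError("rule file must be a mapping with a 'rules' list")
    rules: dict[str, ClassificationRule] = {}
    for entry in doc["rules"]:
        rid = entry.get("id")
        if not rid:
            raise RuleError("rule entry without an id")
        if rid in rules:
            raise RuleError(f"duplicate rule id {rid}")
        kind = entry.get("kind", "smarts")
        expr = None
        if kind == "predicate":
            if "weight" not in entry:
                raise RuleError(f"rule {rid}: predicate rule must declare a weight")
            try:
                expr = parse_predicate(entry["expr"])
            except (PredicateError, KeyError) as exc:
                raise RuleError(f"rule {rid}: bad predicate expr: {exc}") from None
        key = StructuralKey(**entry.get("key", {}))
        rule = ClassificationRule(
            rule_id=rid,
            category_id=entry.get("category", ""),
            kind=kind,
            patterns=list(entry.get("patterns", [])),
            expr=expr,
            weight=int(entry.get("weight", 0)),
            structural_key=key,
            is_substituent=bool(entry.get("substituent", False)),
            substituent_name=entry.get("substituent_name"),
            stereo_specific=bool(entry.get("stereo", False)),
            scope=entry.get("scope", "molecule"),
            positive_examples=list(entry.get("positive", [])),
            negative_examples=list(entry.get("negative", [])),
        )
        if tax is not None and rule.category_id not in tax:
            raise RuleError(f"rule {rid}: unknown category_id {rule.category_id}")
        rule.weight = rule_weight(rule)
        rule.structural_key = compute_structural_key(rule)
        rules[rid] = rule
    preferences = [
        (p["prefer"], p["over"]) for p in doc.get("preferences", [])
    ]
    return RuleSet(rules=rules, preferences=preferences)


def write_rule_file(rs: RuleSet) -> str:
    """Serialize a RuleSet back to the YAML rule format (rule order kept)."""
    entries = []
    for rule in rs.rules.values():
        e: dict = {"id": rule.rule_id, "category": rule.category_id, "kind": rule.kind}
        if rule.kind == "smarts":
            e["patterns"] = list(rule.patterns)
        elif rule.kind == "predicate":
            e["expr"] = rule.expr.unparse()
            e["weight"] = rule.weight
            key = {
                name: val
                for name, val in zip(
                    rule.structural_key.__dataclass_fields__, rule.structural_key.as_tuple()
                )
                if val
            }
            if key:
                e["key"] = key
        if rule.is_substituent:
            e["substituent"] = True
        if rule.substituent_name:
            e["substituent_name"] = rule.substituent_name
        if rule.stereo_specific:
            e["stereo"] = True
        if rule.scope != "molecule":
            e["scope"] = rule.scope
        if rule.positive_examples:
            e["positive"] = list(rule.positive_examples)
        if rule.negative_examples:
            e["negative"] = list(rule.negative_examples)
        entries.append(e)
    doc: dict = {"rules": entries}
    if rs.preferences:
        doc["preferences"] = [
            {"prefer": p, "over": s} for p, s in rs.preferences
        ]
    return yaml.safe_dump(doc, sort_keys=False, width=1000)


# -- validation ----------------------------------------------------------------


@dataclass
class RuleIssue:
    rule_id: str
    code: str
    message: str


def validate_ruleset(rs: RuleSet, tax: Taxonomy) -> list[RuleIssue]:
    """Check category references, preference sanity, and that every rule
    matches all its positive examples and none of its negatives."""
    issues: list[RuleIssue] = []
    for rule in rs.rules.values():
        if rule.category_id not in tax:
            issues.append(
                RuleIssue(rule.rule_id, "dangling-category",
                          f"category {rule.category_id} not in taxonomy")
            )
        if rule.kind == "union":
            continue
        for smi in rule.positive_examples:
            if not match_rule(rule, preprocess(smi)):
                issues.append(
                    RuleIssue(rule.rule_id, "positive-miss",
                              f"positive example {smi} does not match")
                )
        for smi in rule.negative_examples:
            if match_rule(rule, preprocess(smi)):
                issues.append(
                    RuleIssue(rule.rule_id, "negative-hit",
                              f"negative example {smi} matches")
                )
    for preferred, suppressed in rs.preferences:
        for cid in (preferred, suppressed):
            if cid not in tax:
                issues.append(
                    RuleIssue("<preferences>", "dangling-category",
                              f"preference references unknown category {cid}")
                )
    return issues
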
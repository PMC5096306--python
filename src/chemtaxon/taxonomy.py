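"""Hierarchical chemical taxonomy: data model, OBO I/O, and tree algebra.

The taxonomy is a rooted tree of structure-defined categories connected by a
single ``is_a`` relationship.  The root ("Chemical entities") has two children,
the kingdoms (organic vs. inorganic compounds); the next levels are named
SuperClass (depth 2), Class (depth 3) and SubClass (depth 4), with up to seven
further levels below, for a maximum node depth of 11.

Categories are identified by ``CHEMONTID:`` + seven digits.  The file format
is OBO 1.2 ``[Term]`` stanzas (tags: id, name, def, synonym, is_a, xref);
unknown tag lines are preserved verbatim so that read/write round-trips are
lossless.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "Category",
    "Synonym",
    "Taxonomy",
    "TaxonomyError",
    "Xref",
    "parse_obo",
    "write_obo",
    "validate_taxonomy",
]

CATEGORY_ID_PATTERN = re.compile(r"^CHEMONTID:\d{7}$")
MAX_DEPTH = 11

SYNONYM_SCOPES = ("EXACT", "NARROW", "BROAD", "RELATED")


class TaxonomyError(ValueError):
    """Raised for structurally invalid taxonomies or malformed OBO input."""


@dataclass(frozen=True)
class Synonym:
    text: str
    scope: str = "EXACT"

    def __post_init__(self) -> None:
        if self.scope not in SYNONYM_SCOPES:
            raise TaxonomyError(
                f"synonym scope {self.scope!r} is not one of {SYNONYM_SCOPES}"
            )


@dataclass(frozen=True)
class Xref:
    source: str
    foreign_id: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.source}:{self.foreign_id}"


@dataclass
class Category:
    """One taxonomy node.

    ``definition`` carries the human-readable structural criteria used both
    for curation and for generated compound descriptions.  ``extra_tags``
    holds verbatim OBO tag lines this package does not interpret.
    """

    id: str
    name: str
    definition: str = ""
    synonyms: list[Synonym] = field(default_factory=list)
    parent_id: str | None = None
    xrefs: list[Xref] = field(default_factory=list)
    level_hint: str | None = None
    extra_tags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not CATEGORY_ID_PATTERN.match(self.id):
            raise TaxonomyError(
                f"category id {self.id!r} does not match the CHEMONTID:nnnnnnn pattern"
            )


class Taxonomy:
    """Rooted single-parent tree of :class:`Category` nodes."""

    def __init__(self, categories: dict[str, Category], root_id: str):
        self.categories = categories
        self.root_id = root_id
        self._children: dict[str, list[str]] = {cid: [] for cid in categories}
        for cat in categories.values():
            if cat.parent_id is not None:
                if cat.parent_id not in categories:
                    raise TaxonomyError(
                        f"{cat.id} references undeclared parent {cat.parent_id}"
                    )
                self._children[cat.parent_id].append(cat.id)
        for kids in self._children.values():
            kids.sort()
        self._check_tree()
        self._depth_cache: dict[str, int] = {}

    # -- construction helpers -------------------------------------------------

    def _check_tree(self) -> None:
        if self.root_id not in self.categories:
            raise TaxonomyError(f"root id {self.root_id} not among categories")
        if self.categories[self.root_id].parent_id is not None:
            raise TaxonomyError("root category must not have a parent")
        roots = [c.id for c in self.categories.values() if c.parent_id is None]
        if roots != [self.root_id]:
            raise TaxonomyError(
                f"exactly one root expected, found parentless nodes: {sorted(roots)}"
            )
        # every node must reach the root without revisiting a node
        for cid in self.categories:
            seen = []
            cur: str | None = cid
            while cur is not None:
                if cur in seen:
                    cycle = seen[seen.index(cur):] + [cur]
                    raise TaxonomyError(
                        "cycle in is_a relation: " + " -> ".join(cycle)
                    )
                seen.append(cur)
                cur = self.categories[cur].parent_id

    # -- queries --------------------------------------------------------------

    def __contains__(self, cid: str) -> bool:
        return cid in self.categories

    def __len__(self) -> int:
        return len(self.categories)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Taxonomy):
            return NotImplemented
        if self.root_id != other.root_id:
            return False
        if set(self.categories) != set(other.categories):
            return False
        for cid, cat in self.categories.items():
            o = other.categories[cid]
            if (cat.name, cat.definition, cat.parent_id) != (o.name, o.definition, o.parent_id):
                return False
            if cat.synonyms != o.synonyms or cat.xrefs != o.xrefs:
                return False
        return True

    def category(self, cid: str) -> Category:
        try:
            return self.categories[cid]
        except KeyError:
            raise TaxonomyError(f"unknown category id {cid!r}") from None

    def children(self, cid: str) -> list[str]:
        self.category(cid)
        return list(self._children[cid])

    def ancestors(self, cid: str) -> list[str]:
        """Path from the root down to ``cid``'s parent (root first).

        Empty for the root itself; ``len(ancestors(x)) == depth(x)``.
        """
        self.category(cid)
        path: list[str] = []
        cur = self.categories[cid].parent_id
        while cur is not None:
            path.append(cur)
            cur = self.categories[cur].parent_id
        path.reverse()
        return path

    def depth(self, cid: str) -> int:
        if cid not in self._depth_cache:
            self._depth_cache[cid] = len(self.ancestors(cid))
        return self._depth_cache[cid]

    def max_depth(self) -> int:
        return max(self.depth(cid) for cid in self.categories)

    def is_ancestor(self, ancestor_id: str, cid: str) -> bool:
        """True when ``ancestor_id`` lies strictly above ``cid``."""
        return ancestor_id in self.ancestors(cid)

    def kingdoms(self) -> list[str]:
        return self.children(self.root_id)

    def kingdom_of(self, cid: str) -> str | None:
        """The depth-1 ancestor of ``cid`` (or ``cid`` itself if a kingdom)."""
        if self.depth(cid) == 1:
            return cid
        anc = self.ancestors(cid)
        return anc[1] if len(anc) > 1 else None

    def reduce_to_antichain(self, ids: set[str] | frozenset[str]) -> set[str]:
        """Drop every member that is an ancestor of another member.

        The survivors carry the most specific information; the result is an
        antichain under the ancestor relation and the operation is idempotent.
        """
        ids = set(ids)
        for cid in ids:
            self.category(cid)
        ancestors_of_members: set[str] = set()
        for cid in ids:
            ancestors_of_members.update(self.ancestors(cid))
        return {cid for cid in ids if cid not in ancestors_of_members}

    def find_by_name(self, name: str) -> Category:
        for cat in self.categories.values():
            if cat.name == name:
                return cat
        raise TaxonomyError(f"no category named {name!r}")


# -- validation ----------------------------------------------------------------


@dataclass
class ValidationIssue:
    code: str
    message: str


def validate_taxonomy(tax: Taxonomy) -> list[ValidationIssue]:
    """Report violations of the structural contract.

    Checks: CHEMONTID format, tree-ness (edge count), the depth-11 bound,
    kingdom partition under the root, and malformed xref sources.  An empty
    report means the taxonomy is well-formed.
    """
    issues: list[ValidationIssue] = []
    n_edges = sum(1 for c in tax.categories.values() if c.parent_id is not None)
    if n_edges != len(tax.categories) - 1:
        issues.append(
            ValidationIssue("tree", f"{n_edges} edges for {len(tax.categories)} nodes")
        )
    for cat in tax.categories.values():
        if not CATEGORY_ID_PATTERN.match(cat.id):
            issues.append(ValidationIssue("id-format", f"malformed id {cat.id!r}"))
        for xref in cat.xrefs:
            if xref.source not in ("CHEBI", "LIPIDMAPS", "MeSH"):
                issues.append(
                    ValidationIssue(
                        "xref-source",
                        f"{cat.id} has xref with unknown source {xref.source!r}",
                    )
                )
    deepest = tax.max_depth()
    if deepest > MAX_DEPTH:
        issues.append(
            ValidationIssue("depth", f"maximum depth {deepest} exceeds bound {MAX_DEPTH}")
        )
    kingdoms = tax.kingdoms()
    if len(kingdoms) != 2:
        issues.append(
            ValidationIssue(
                "kingdoms", f"root has {len(kingdoms)} children, expected 2 kingdoms"
            )
        )
    return issues


# -- OBO 1.2 I/O ----------------------------------------------------------------

_SYNONYM_RE = re.compile(r'^"(?P<text>(?:[^"\\]|\\.)*)"\s+(?P<scope>\w+)')
_DEF_RE = re.compile(r'^"(?P<text>(?:[^"\\]|\\.)*)"')
_KNOWN_TAGS = ("id", "name", "def", "synonym", "is_a", "xref")


def _unescape(text: str) -> str:
    return text.replace('\\"', '"').replace("\\\\", "\\")


def _escape(text: str) -> str:
    return text.replace("\\", "\\\\").replace('"', '\\"')


def parse_obo(obo_text: str) -> Taxonomy:
    """Parse OBO 1.2 text into a validated :class:`Taxonomy`.

    Only ``[Term]`` stanzas are interpreted.  A term carrying two ``is_a``
    lines, a duplicate id, a dangling ``is_a`` reference, or a parent cycle is
    an error: the taxonomy is a tree by contract.
    """
    categories: dict[str, Category] = {}
    stanza: list[str] | None = None
    stanzas: list[list[str]] = []
    for raw in obo_text.splitlines():
        line = raw.strip()
        if line == "[Term]":
            if stanza is not None:
                stanzas.append(stanza)
            stanza = []
        elif line.startswith("["):  # other stanza types end a term
            if stanza is not None:
                stanzas.append(stanza)
            stanza = None
        elif stanza is not None and line:
            stanza.append(line)
    if stanza is not None:
        stanzas.append(stanza)

    parent_of: dict[str, str] = {}
    for lines in stanzas:
        cid: str | None = None
        name = ""
        definition = ""
        synonyms: list[Synonym] = []
        xrefs: list[Xref] = []
        extra: list[str] = []
        parents: list[str] = []
        for line in lines:
            if ":" not in line:
                extra.append(line)
                continue
            tag, _, value = line.partition(":")
            tag = tag.strip()
            value = value.strip()
            if tag == "id":
                cid = value
            elif tag == "name":
                name = value
            elif tag == "def":
                m = _DEF_RE.match(value)
                if not m:
                    raise TaxonomyError(f"malformed def line: {line!r}")
                definition = _unescape(m.group("text"))
            elif tag == "synonym":
                m = _SYNONYM_RE.match(value)
                if not m:
                    raise TaxonomyError(f"malformed synonym line: {line!r}")
                synonyms.append(Synonym(_unescape(m.group("text")), m.group("scope")))
            elif tag == "is_a":
                parents.append(value.split("!")[0].strip())
            elif tag == "xref":
                src, _, fid = value.partition(":")
                xrefs.append(Xref(src.strip(), fid.strip()))
            else:
                extra.append(line)
        if cid is None:
            raise TaxonomyError("term stanza without an id tag")
        if cid in categories:
            raise TaxonomyError(f"duplicate category id {cid}")
        if len(parents) > 1:
            raise TaxonomyError(
                f"{cid}: multiple parents violate tree constraint ({', '.join(parents)})"
            )
        if parents:
            parent_of[cid] = parents[0]
        categories[cid] = Category(
            id=cid,
            name=name,
            definition=definition,
            synonyms=synonyms,
            parent_id=None,
            xrefs=xrefs,
            extra_tags=extra,
        )

    for cid, pid in parent_of.items():
        if pid not in categories:
            raise TaxonomyError(f"{cid}: is_a references undeclared id {pid}")
        categories[cid].parent_id = pid

    roots = [c.id for c in categories.values() if c.parent_id is None]
    if not roots:
        raise TaxonomyError("no root category (every term has an is_a line)")
    if len(roots) > 1:
        raise TaxonomyError(f"multiple parentless terms: {sorted(roots)}")
    return Taxonomy(categories, roots[0])


def write_obo(tax: Taxonomy) -> str:
    """Serialize to OBO 1.2; terms in ascending id order for byte stability."""
    out: list[str] = [
        "format-version: 1.2",
        "ontology: chemtaxon",
        "",
    ]
    for cid in sorted(tax.categories):
        cat = tax.categories[cid]
        out.append("[Term]")
        out.append(f"id: {cat.id}")
        out.append(f"name: {cat.name}")
        if cat.definition:
            out.append(f'def: "{_escape(cat.definition)}" []')
        for syn in cat.synonyms:
            out.append(f'synonym: "{_escape(syn.text)}" {syn.scope} []')
        for xref in cat.xrefs:
            out.append(f"xref: {xref.source}:{xref.foreign_id}")
        if cat.parent_id is not None:
            out.append(f"is_a: {cat.parent_id} ! {tax.categories[cat.parent_id].name}")
        for line in cat.extra_tags:
            out.append(line)
        out.append("")
    return "\n".join(out)
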
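# Methods

This note documents the models, conventions, and numerical choices behind
`chemtaxon`, and what its fixtures do and do not demonstrate.

## Taxonomy model

The taxonomy is a strict tree: every category except the root has exactly
one parent under the *is_a* relation. A term with two `is_a` lines is a
hard parse error, not a warning — the direct-parent semantics (one primary
label per compound, all other assignments reported as alternative parents)
depend on unambiguous ancestor chains. Depth is defined structurally
(root = 0, kingdoms = 1, …) and the validator enforces the 11-level bound.
Ordering is deterministic everywhere (ascending `CHEMONTID`), so OBO output
is byte-stable and safe to diff or fingerprint.

The OBO dialect is OBO 1.2 `[Term]` stanzas with `id`, `name`, `def`,
`synonym` (scope keyword after the quoted text, one of EXACT / NARROW /
BROAD / RELATED), `is_a`, and `xref`. Unknown tag lines are carried through
verbatim so round-trips are lossless. The parser is written in-package:
the contract here includes strict tree-shape errors (duplicate id, multiple
parents, dangling reference, cycle) and verbatim unknown-tag preservation
for writing, which general-purpose OBO readers do not provide in this
combination.

Seed category ids are self-assigned within the `CHEMONTID` namespace and
are **not** canonical, except for a handful whose published values are
well-known and reused verbatim (`CHEMONTID:0002450` primary amines;
`0003027`/`0003232`/`0003233` for the 3-hydroxysteroid family;
`0004377` imidazo[1,2-a]pyrimidines).

## Rule language

Three rule kinds:

- **smarts** — one or more SMARTS patterns; the rule fires when any pattern
  has at least one embedding (superstructure search).
- **predicate** — a boolean expression over `AtomCount(element)`,
  `TotalAtomCount()`, `RingCount()`, `AromaticRingCount()`, and
  `MolecularFormula(...)`, with `+`, `*`, integer constants, comparisons,
  and `and`/`or`/`not`. The grammar is closed; rule files cannot execute
  code. Hydrogen counts include implicit hydrogens.
- **union** — no matching logic; the category is assigned when any
  descendant category is assigned. Used where a class is defined by its
  members (phenylpropanoids, peptides, hydroxysteroids, ...).

**Weights.** A rule's feature weight is the number of non-hydrogen atoms of
the feature it describes. For SMARTS rules this is computed: the minimum
over patterns of the pattern's heavy-atom count, descending into top-level
recursive-SMARTS alternatives (`[$( .. ),$( .. )]` counts one alternative,
so the thiazole rule weighs 5). For predicate rules no pattern exists, so
the weight is declared in the rule file as the heavy-atom count of the
smallest compound meant to satisfy the constraints. The seed alkane rule
declares 3 (propane): methane and ethane satisfy the formula, but letting
the alkane feature weigh 1 would make it lose ties it should win against
other single-atom features; the declared value records the smallest
*typical* member. The rule-set validator enforces that no weight exceeds
the heavy-atom count of the rule's smallest positive example.

**Structural keys.** Seven counts (cycles, heterocycles, ring atoms, ring
heteroatoms, halogen atoms, fused rings, total heteroatoms) computed from
the rule's minimal pattern interpreted as a molecular graph; predicate and
union rules declare a key (default all-zero). A ring counts as *fused* if
it shares at least one bond with another ring. Query atoms with no definite
element (`*`, multi-element alternatives) are treated as carbon for the
hetero counts — keys are tie-breakers, not chemistry, and this keeps them
total.

**Aromaticity and matching.** Queries are normalized and aromatized with
the toolkit's default model during standardization. Library patterns are
matched against the aromatized form first and against a kekulized copy
second, so patterns written with explicit alternating bonds (the common
kekulé drawing of heteroaromatic rings, as in the thiazole pattern) still
hit aromatized queries. Stereo-specific rules (the 3-alpha/3-beta
hydroxysteroid patterns) match with chirality enforcement, so
stereo-stripped input falls back to the stereo-agnostic parent category —
a canonical-structure query can only ever be classified as precisely as
its annotation allows.

**Mixture-scope rules.** Rules flagged `scope: mixture` (salt categories
written as dotted SMARTS over two components) are evaluated only on
multi-component entities, against the whole entity.

## Classification pipeline

1. **Preprocess** — parse, normalize functional-group drawings (e.g. both
   nitro forms converge), sanitize, aromatize, split components
   (descending heavy-atom count, ties by canonical SMILES). Idempotent.
2. **Kingdom** — organic iff the structure contains carbon and is not on
   the configured inorganic exception list: carbon mon-/dioxide, carbon
   mono-/disulfide, hydrogen cyanide and cyanide ion as exact structures,
   plus SMARTS for non-hydrocarbyl cyanide/isocyanide derivatives. The
   list is configuration, not code, because its tail (which derivatives
   count) is a curatorial choice.
3. **Features → categories → antichain** — all rules evaluated, union
   closure applied, matched categories restricted to the assigned kingdom,
   then reduced so no retained category is an ancestor of another.
4. **Direct parent** — maximal weight; ties broken lexicographically on
   the structural key in its listed field order, larger values winning;
   remaining ties broken by ascending category id, which guarantees a
   deterministic result. Preference pairs remove the suppressed category
   from the *selection* pool only — it remains a legitimate alternative
   parent in the report.

A molecule matching no rule is reported as a kingdom-only "shallow"
classification rather than an error; partial rule sets would otherwise be
unusable. Mixtures are classified per component and as a whole; if any
component is organic the merged result is rooted in the organic kingdom
and inorganic-branch categories are dropped from the merged candidate set.
The molecular framework label (aromatic/aliphatic ×
acyclic/homomonocyclic/heteromonocyclic/homopolycyclic/heteropolycyclic)
does not apply to mixtures.

## Peptide input

FASTA protein records are converted to linear peptide SMILES: standard
backbone amides, free termini, L-configured alpha carbons (glycine
achiral, proline contributing its ring). Side-chain stereocenters
(Ile, Thr) are left unspecified. Sequence typing is heuristic because the
nucleotide and amino-acid alphabets overlap: a sequence over
`{A,C,G,T,U,N}` is treated as a nucleotide (and rejected) only when it is
at least 8 letters long or contains `U`; shorter all-ACGT strings are read
as peptides. Free amino acids (length-1 input) are out of the adapter's
scope.

## Seed fixtures and what they show

The seed taxonomy (82 categories, maximum depth 6) and rule set (78 rules,
one preference pair) are scaled-down but structurally faithful: real
category names and definitions, the classic thiazole SMARTS and alkane
formula predicate verbatim, a deep peptide branch, a stereo steroid
branch, union categories, and salt/mixture rules. The synthetic generators
produce alkane trees (CnH2n+2 by construction) and substituted scaffolds
(benzene, thiazole, pyridine, glucose, flavone) deterministically from a
seed. The golden corpus (88 molecules) records hand-derived expectations —
kingdom, direct parent, the complete alternative-parent set, framework —
for every rule family and edge case (exceptions list, shallow fallback,
stereo fallback, mixtures, preference path).

What passing these fixtures does **not** show: behavior at the scale of a
full production taxonomy (thousands of categories, >9000 patterns),
coverage of categories that need name-based or Markush-style matching
(out of scope here; Markush-era categories are approximated by enumerated
SMARTS), or agreement with any external curated database. The acceptance
checks are about mechanism correctness, not chemical coverage.

## Numerical and design choices

- Tie-break order/direction for direct-parent selection (key fields in
  listed order, larger wins, then ascending id) is a convention chosen for
  determinism; no ordering claim is inherited from elsewhere.
- Degenerate inputs: empty structures and unparseable records raise typed
  errors carrying the offending record; batch readers convert these to
  per-record error entries unless `--strict`.
- The unsaturated-hydrocarbon predicate discounts `2 * RingCount()`
  hydrogens before testing for double/triple bonds, since ring closure
  reduces the hydrogen count exactly as a double bond does.
- The result cache keys on the InChIKey of the standardized structure
  (canonical SMILES as fallback) and stamps entries with a SHA-256
  fingerprint of the taxonomy and rule-file texts; any knowledge-base edit
  invalidates all prior entries by construction.
- JSON output is validated through a pydantic document model; the shipped
  `data/result_schema.json` is generated from that model, so writer and
  schema cannot drift.
- Problem sizes in the test suite (100–120 random subsets for the
  reduction oracle, 20 molecules × 20 permutations for invariance, 50
  hydrocarbons for the alkane oracle) were chosen to exercise the
  combinatorics thoroughly while keeping the default suite fast.

## Known limitations

- SMARTS-expressible rules only: categories defined by variable-count
  constraints (e.g. "exactly three conjugated double bonds anywhere") need
  enumeration and are not representable compactly.
- The kingdom exception list defaults to the classic carbon-containing
  species; exotic organometallic edge cases are a configuration matter.
- Sequence-type detection for FASTA is heuristic (see above).
- IUPAC-name input is not supported; names must be converted to structures
  upstream.
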
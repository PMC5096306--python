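# chemtaxon

Rule-based hierarchical chemical classification: a computable chemical
taxonomy, a structural rule engine, and a classifier that assigns every
input structure a full taxonomic lineage.

## The problem

Chemistry lacks a universally adopted, *computable* classification scheme.
Curated resources assign compounds to classes by hand, which is slow,
inconsistent, and covers a vanishing fraction of known chemical space.
`chemtaxon` implements the alternative: every category in a hierarchical
chemical taxonomy is bound to an explicit, machine-evaluable structural
rule, so classification of an arbitrary structure is fully automatic and
reproducible.

It is aimed at cheminformaticians and database curators who need consistent
class labels — for annotation, ontology-based enrichment, search
facets, or automatic compound descriptions.

## The model

**Taxonomy.** A rooted tree of categories connected by a single *is_a*
relation. The root ("Chemical entities") splits into two kingdoms, organic
and inorganic; the next levels are the SuperClass (depth 2), Class (3), and
SubClass (4), with up to seven further levels (maximum depth 11). The
taxonomy is read and written as OBO 1.2; ids follow the
`CHEMONTID:nnnnnnn` convention.

**Rules.** A category's rule is one of:

- a set of **SMARTS patterns** matched by superstructure search (the
  pattern must embed in the query), e.g. the 1,3-thiazole ring
  `[$([#16]-1-[#6]=[#6]-[#6]=[#7]-1),$([#16]-1-[#6]=[#6]-[#7]=[#6]-1)]`;
- a **predicate** over whole-molecule properties in a closed grammar, e.g.
  alkanes:
  `RingCount() = 0 ∧ AtomCount(C) > 0 ∧ AtomCount(C)+AtomCount(H) = TotalAtomCount() ∧ AtomCount(H) = 2·AtomCount(C)+2`;
- a **union**: the category holds whenever any descendant category holds
  (used for biosynthetically defined groups like "Phenylpropanoids and
  polyketides").

Every rule carries a *feature weight* — the number of non-hydrogen atoms of
the feature it recognizes (computed from the pattern, or declared for
predicates as the size of the smallest qualifying compound) — and a
seven-count *structural key* (cycles, heterocycles, ring atoms, ring
heteroatoms, halogens, fused rings, heteroatoms).

**Classification** proceeds in four steps:

1. *Preprocess*: parse (SMILES/InChI/molfile), normalize functional groups,
   aromatize, split disconnected components.
2. *Extract features*: evaluate every rule; close over union categories.
3. *Assign and reduce*: map matched rules to categories and reduce the set
   to an antichain — whenever both an ancestor and its descendant matched,
   keep only the descendant.
4. *Select the direct parent*: the candidate with the largest feature
   weight; ties break on the structural key field by field (larger wins),
   then on ascending id. Configured preference pairs override size (e.g.
   "flavonoid glycosides" is selected over "glycosides").

The direct parent's ancestor chain yields the kingdom/superclass/class/
subclass slots; the remaining candidates are reported as *alternative
parents*. Results also carry the substituent list, a *molecular framework*
label (aromaticity × ring topology), cross-references of the assigned
categories, and a generated English description.

A seed taxonomy (82 categories) and rule set (78 rules) ship with the
package, along with deterministic molecule generators and a golden corpus,
so everything is testable offline.

## Worked example

```sh
printf 'NCC(=O)NCC(O)=O glycylglycine\nc1cscn1 thiazole\n' > demo.smi
chemtaxon classify --input demo.smi --output demo.json
```

The JSON result for glycylglycine reports:

- direct parent **Dipeptides** — the dipeptide backbone (9 heavy atoms) is
  the largest recognized feature;
- lineage kingdom *Organic compounds* → superclass *Organic acids and
  derivatives* → class *Carboxylic acids and derivatives* → subclass
  *Amino acids, peptides, and analogues*;
- alternative parents *Carboxylic acids*, *Carboxamides*, *Carbonyl
  compounds*, *Primary amines* — smaller features with no
  ancestor–descendant relation to the direct parent or each other;
- molecular framework `aliphatic acyclic compound`;
- the description: "NCC(=O)NCC(O)=O belongs to the class of compounds
  known as dipeptides. Compounds containing exactly two amino-acid
  residues joined by a single peptide bond. Structurally, it is an
  aliphatic acyclic compound. It carries the following structural
  features: carbonyl group, carboxamide group, carboxylic acid group,
  primary amine."

For thiazole the direct parent is **Thiazoles** (the printed five-membered
ring pattern, weight 5) with alternative parents *Organosulfur compounds*
and *Organonitrogen compounds* and framework
`aromatic heteromonocyclic compound`.

Other CLI commands: `chemtaxon taxonomy validate|stats`,
`chemtaxon rules validate`, `chemtaxon fixtures generate --out DIR`.
Peptide FASTA input is accepted (`--format fasta`); a `--cache` file makes
repeat runs a lookup instead of a recomputation.

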
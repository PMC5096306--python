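"""Seed chemical taxonomy (~80 categories) shipped with the package.

A deliberately small but structurally faithful tree: a root, the two
kingdoms (organic/inorganic), a spread of superclasses, and enough depth
(one branch reaches depth 6) to exercise lineage, reduction, and
direct-parent logic.  Category ids are self-assigned within the CHEMONTID
namespace and are NOT canonical identifiers, with a handful of
exceptions whose published ids are reused verbatim (primary amines and the
3-hydroxysteroid family).
"""

from __future__ import annotations

from ..taxonomy import Category, Synonym, Taxonomy, Xref, parse_obo, write_obo

__all__ = ["build_seed_taxonomy", "get_seed_taxonomy", "ROOT_ID"]

ROOT_ID = "CHEMONTID:0000000"

# (name, parent name or None, definition, [(synonym, scope)], [(src, id)], explicit id)
_E: list[tuple] = [
    ("Chemical entities", None,
     "Any molecular entity, molecule, ion, or mixture thereof with a definable chemical structure",
     [], [("CHEBI", "24431")], ROOT_ID),
    # ---- kingdoms
    ("Organic compounds", "Chemical entities",
     "Compounds whose structure contains one or more carbon atoms, excluding a small set of "
     "carbon-containing species classified as inorganic by convention",
     [("organic molecular entities", "RELATED")], [("CHEBI", "50860")], None),
    ("Inorganic compounds", "Chemical entities",
     "Compounds that contain no carbon, together with carbon oxides, carbon sulfides, and "
     "cyanide or isocyanide species and their non-hydrocarbyl derivatives",
     [], [], None),
    # ---- organic superclasses
    ("Hydrocarbons", "Organic compounds",
     "Organic compounds made up exclusively of carbon and hydrogen atoms", [], [], None),
    ("Organoheterocyclic compounds", "Organic compounds",
     "Organic compounds containing a ring made up of carbon and at least one other element", [], [], None),
    ("Benzenoids", "Organic compounds",
     "Aromatic compounds containing one or more benzene rings", [], [], None),
    ("Organic acids and derivatives", "Organic compounds",
     "Organic compounds with at least one acidic functional group, or derivatives thereof", [], [], None),
    ("Organic oxygen compounds", "Organic compounds",
     "Organic compounds containing at least one oxygen atom", [], [], None),
    ("Organic nitrogen compounds", "Organic compounds",
     "Organic compounds containing at least one nitrogen atom", [], [], None),
    ("Organosulfur compounds", "Organic compounds",
     "Organic compounds containing at least one carbon-sulfur bond", [], [], None),
    ("Organohalogen compounds", "Organic compounds",
     "Organic compounds containing at least one carbon-halogen bond", [], [], None),
    ("Lipids and lipid-like molecules", "Organic compounds",
     "Fatty acids, their conjugates and derivatives, and other hydrophobic or amphipathic "
     "molecules of biological origin", [], [], None),
    ("Phenylpropanoids and polyketides", "Organic compounds",
     "Organic compounds synthesized from the amino acid phenylalanine or from the "
     "decarboxylative condensation of malonyl-CoA, described as the union of their subcategories",
     [], [], None),
    ("Organic salts", "Organic compounds",
     "Ionic compounds in which at least one of the constituent ions is organic", [], [], None),
    # ---- inorganic superclasses
    ("Homogeneous metal compounds", "Inorganic compounds",
     "Inorganic compounds made up exclusively of metal atoms", [], [], None),
    ("Homogeneous non-metal compounds", "Inorganic compounds",
     "Inorganic compounds made up exclusively of non-metal atoms", [], [], None),
    ("Inorganic salts", "Inorganic compounds",
     "Ionic compounds in which all constituent ions are inorganic", [], [], None),
    # ---- hydrocarbons
    ("Saturated hydrocarbons", "Hydrocarbons",
     "Hydrocarbons containing only carbon-carbon single bonds, described as the union of "
     "their subcategories", [], [], None),
    ("Alkanes", "Saturated hydrocarbons",
     "Acyclic branched or unbranched hydrocarbons having the general formula CnH2n+2",
     [("paraffins", "RELATED")], [("CHEBI", "18310")], None),
    ("Cycloalkanes", "Saturated hydrocarbons",
     "Saturated monocyclic hydrocarbons with the general formula CnH2n, with or without "
     "alkyl side chains", [], [], None),
    ("Unsaturated hydrocarbons", "Hydrocarbons",
     "Non-aromatic hydrocarbons containing at least one carbon-carbon double or triple bond",
     [], [], None),
    ("Alkenes", "Unsaturated hydrocarbons",
     "Acyclic hydrocarbons containing exactly one carbon-carbon double bond, with the "
     "general formula CnH2n", [("olefins", "RELATED")], [], None),
    # ---- organoheterocyclic
    ("Azoles", "Organoheterocyclic compounds",
     "Compounds containing a five-membered aromatic heterocycle with at least one nitrogen atom",
     [], [], None),
    ("Thiazoles", "Azoles",
     "Heterocyclic compounds containing a five-member aromatic ring made up of one sulfur "
     "atom, one nitrogen atom, and three carbon atoms",
     [("1,3-thiazoles", "EXACT")], [("CHEBI", "38418")], None),
    ("Imidazoles", "Azoles",
     "Compounds containing an aromatic five-membered 1,3-diazole ring",
     [("1,3-diazoles", "EXACT")], [], None),
    ("Pyrazoles", "Azoles",
     "Compounds containing an aromatic five-membered 1,2-diazole ring", [], [], None),
    ("Oxazoles", "Azoles",
     "Compounds containing an aromatic five-membered 1,3-oxazole ring with one oxygen and "
     "one nitrogen atom", [], [], None),
    ("Pyridines and derivatives", "Organoheterocyclic compounds",
     "Compounds containing a six-membered aromatic ring with one ring nitrogen atom",
     [("azines", "BROAD")], [], None),
    ("Pyrimidines and derivatives", "Organoheterocyclic compounds",
     "Compounds containing a six-membered aromatic ring with two ring nitrogen atoms in the "
     "1,3 arrangement", [], [], None),
    ("Imidazo[1,2-a]pyrimidines", "Organoheterocyclic compounds",
     "Compounds containing an imidazole ring fused to a pyrimidine ring at positions 1 and 2",
     [], [], "CHEMONTID:0004377"),
    ("Dioxanes", "Organoheterocyclic compounds",
     "Compounds containing a six-membered saturated ring with two oxygen atoms", [], [], None),
    ("1,2-Dioxanes", "Dioxanes",
     "Dioxanes in which the two ring oxygen atoms are adjacent", [], [], None),
    ("1,4-Dioxanes", "Dioxanes",
     "Dioxanes in which the two ring oxygen atoms are in the para arrangement", [], [], None),
    ("Furans", "Organoheterocyclic compounds",
     "Compounds containing an aromatic five-membered ring with one oxygen atom", [], [], None),
    ("Thiophenes", "Organoheterocyclic compounds",
     "Compounds containing an aromatic five-membered ring with one sulfur atom", [], [], None),
    # ---- benzenoids
    ("Benzene and substituted derivatives", "Benzenoids",
     "Compounds containing a monocyclic benzene ring", [], [], None),
    ("Benzoic acids", "Benzene and substituted derivatives",
     "Compounds containing a carboxylic acid group attached directly to a benzene ring",
     [], [], None),
    ("Anilines", "Benzene and substituted derivatives",
     "Compounds containing a primary amine group attached directly to a benzene ring",
     [], [], None),
    ("Phenols", "Benzenoids",
     "Compounds containing a hydroxyl group attached directly to a benzene ring", [], [], None),
    ("Naphthalenes", "Benzenoids",
     "Compounds containing two fused benzene rings", [], [], None),
    # ---- organic acids
    ("Carboxylic acids and derivatives", "Organic acids and derivatives",
     "Compounds containing a carboxyl group or a derivative thereof such as an ester or amide",
     [], [], None),
    ("Carboxylic acids", "Carboxylic acids and derivatives",
     "Compounds containing a carboxyl group, -C(=O)OH, or its conjugate base",
     [("carboxylic acid", "NARROW")], [("CHEBI", "33575")], None),
    ("Carboxamides", "Carboxylic acids and derivatives",
     "Compounds containing a carboxamide group, -C(=O)N", [], [("CHEBI", "35358")], None),
    ("Amino acids, peptides, and analogues", "Carboxylic acids and derivatives",
     "Amino acids, oligomers thereof joined by peptide bonds, and their structural analogues, "
     "described as the union of their subcategories", [], [], None),
    ("Amino acids", "Amino acids, peptides, and analogues",
     "Compounds containing both a free amine group and a carboxylic acid group attached to "
     "the same saturated carbon atom", [], [], None),
    ("Peptides", "Amino acids, peptides, and analogues",
     "Compounds containing two or more amino-acid residues joined by peptide bonds, described "
     "as the union of their subcategories", [], [], None),
    ("Dipeptides", "Peptides",
     "Compounds containing exactly two amino-acid residues joined by a single peptide bond",
     [], [], None),
    ("Tripeptides", "Peptides",
     "Compounds containing exactly three amino-acid residues joined by two peptide bonds",
     [], [], None),
    # ---- organic oxygen
    ("Organooxygen compounds", "Organic oxygen compounds",
     "Organic compounds containing at least one carbon-oxygen bond", [], [], None),
    ("Alcohols and polyols", "Organooxygen compounds",
     "Compounds containing a hydroxyl group attached to a saturated carbon atom", [], [], None),
    ("Primary alcohols", "Alcohols and polyols",
     "Compounds containing a hydroxyl group attached to a saturated carbon atom that carries "
     "two hydrogen atoms", [], [], None),
    ("Secondary alcohols", "Alcohols and polyols",
     "Compounds containing a hydroxyl group attached to a saturated carbon atom that carries "
     "one hydrogen atom and two carbon substituents", [], [], None),
    ("Tertiary alcohols", "Alcohols and polyols",
     "Compounds containing a hydroxyl group attached to a saturated carbon atom that carries "
     "three carbon substituents", [], [], None),
    ("Carbonyl compounds", "Organooxygen compounds",
     "Compounds containing a carbon atom double-bonded to an oxygen atom", [], [], None),
    ("Ketones", "Carbonyl compounds",
     "Compounds containing a carbonyl group bonded to two carbon atoms", [], [], None),
    ("Aldehydes", "Carbonyl compounds",
     "Compounds containing a carbonyl group bonded to at least one hydrogen atom", [], [], None),
    ("Ethers", "Organooxygen compounds",
     "Compounds containing an oxygen atom bonded to two saturated carbon atoms", [], [], None),
    ("Glycosides", "Organooxygen compounds",
     "Compounds in which a sugar ring is bound to another moiety via its anomeric carbon "
     "through a glycosidic oxygen bond", [], [("CHEBI", "24400")], None),
    # ---- organic nitrogen
    ("Organonitrogen compounds", "Organic nitrogen compounds",
     "Organic compounds containing at least one carbon-nitrogen bond", [], [], None),
    ("Amines", "Organonitrogen compounds",
     "Compounds in which a nitrogen atom carrying no acyl substituent is bonded to one or "
     "more carbon atoms", [], [], None),
    ("Primary amines", "Amines",
     "Compounds containing a nitrogen atom bonded to exactly one carbon atom and two hydrogen atoms",
     [("primary amine", "EXACT")], [("CHEBI", "32877")], "CHEMONTID:0002450"),
    ("Secondary amines", "Amines",
     "Compounds containing a nitrogen atom bonded to exactly two carbon atoms and one hydrogen atom",
     [], [], None),
    ("Tertiary amines", "Amines",
     "Compounds containing a nitrogen atom bonded to exactly three carbon atoms", [], [], None),
    # ---- organosulfur / organohalogen
    ("Thiols", "Organosulfur compounds",
     "Compounds containing a sulfhydryl group, -SH, attached to a carbon atom", [], [], None),
    ("Organochlorides", "Organohalogen compounds",
     "Organic compounds containing at least one carbon-chlorine bond", [], [], None),
    ("Organofluorides", "Organohalogen compounds",
     "Organic compounds containing at least one carbon-fluorine bond", [], [], None),
    # ---- lipids
    ("Steroids and steroid derivatives", "Lipids and lipid-like molecules",
     "Compounds based on the fused tetracyclic cyclopenta[a]phenanthrene skeleton",
     [], [("LIPIDMAPS", "ST")], None),
    ("Hydroxysteroids", "Steroids and steroid derivatives",
     "Steroids carrying at least one hydroxyl group on the steroid nucleus, described as the "
     "union of their subcategories", [], [], None),
    ("3-hydroxysteroids", "Hydroxysteroids",
     "Steroids carrying a hydroxyl group at the 3-position of the steroid nucleus",
     [], [], "CHEMONTID:0003027"),
    ("3-alpha-hydroxysteroids", "3-hydroxysteroids",
     "3-hydroxysteroids in which the 3-hydroxyl group is in the alpha orientation",
     [], [], "CHEMONTID:0003232"),
    ("3-beta-hydroxysteroids", "3-hydroxysteroids",
     "3-hydroxysteroids in which the 3-hydroxyl group is in the beta orientation",
     [], [], "CHEMONTID:0003233"),
    ("Fatty acyls", "Lipids and lipid-like molecules",
     "Fatty acids and their derivatives, described as the union of their subcategories",
     [], [("LIPIDMAPS", "FA")], None),
    ("Fatty acids and conjugates", "Fatty acyls",
     "Aliphatic monocarboxylic acids with a chain of at least six carbon atoms", [], [], None),
    # ---- phenylpropanoids
    ("Flavonoids", "Phenylpropanoids and polyketides",
     "Compounds based on the 2-phenylchromen-4-one skeleton and its derivatives, described "
     "as the union of their subcategories", [], [], None),
    ("Flavones", "Flavonoids",
     "Compounds containing the 2-phenylchromen-4-one (2-phenyl-4H-chromen-4-one) skeleton",
     [], [], None),
    ("Flavonoid glycosides", "Flavonoids",
     "Compounds containing a flavonoid moiety glycosidically linked to a carbohydrate moiety",
     [], [], None),
    # ---- organic salts
    ("Organic chlorine salts", "Organic salts",
     "Salts made up of an organic component and a free chloride anion",
     [("organic chloride salts", "RELATED")], [], None),
    # ---- inorganic classes
    ("Homogeneous alkali metal compounds", "Homogeneous metal compounds",
     "Compounds made up exclusively of alkali metal atoms or ions", [], [], None),
    ("Homogeneous transition metal compounds", "Homogeneous metal compounds",
     "Compounds made up exclusively of transition metal atoms or ions", [], [], None),
    ("Non-metal oxides", "Homogeneous non-metal compounds",
     "Inorganic compounds in which an oxygen atom is double-bonded to a non-metal atom", [], [], None),
    ("Homogeneous halogens", "Homogeneous non-metal compounds",
     "Free halogen atoms or halide ions not bound to any other element", [], [], None),
    ("Alkali metal salts", "Inorganic salts",
     "Ionic compounds made up of an alkali metal cation and an inorganic anion", [], [], None),
]


def build_seed_taxonomy() -> str:
    """Construct the seed taxonomy and return its OBO 1.2 text."""
    used = {e[5] for e in _E if e[5]}
    categories: dict[str, Category] = {}
    by_name: dict[str, str] = {}
    counter = 1
    for name, parent, definition, synonyms, xrefs, explicit in _E:
        if explicit:
            cid = explicit
        else:
            while f"CHEMONTID:{counter:07d}" in used:
                counter += 1
            cid = f"CHEMONTID:{counter:07d}"
            used.add(cid)
            counter += 1
        if name in by_name:
            raise ValueError(f"duplicate seed category name {name!r}")
        by_name[name] = cid
        categories[cid] = Category(
            id=cid,
            name=name,
            definition=definition,
            synonyms=[Synonym(t, s) for t, s in synonyms],
            parent_id=by_name[parent] if parent else None,
            xrefs=[Xref(src, fid) for src, fid in xrefs],
        )
    tax = Taxonomy(categories, by_name["Chemical entities"])
    return write_obo(tax)


_CACHE: Taxonomy | None = None


def get_seed_taxonomy() -> Taxonomy:
    """Parsed seed taxonomy (cached; the OBO text is the source of truth)."""
    global _CACHE
    if _CACHE is None:
        _CACHE = parse_obo(build_seed_taxonomy())
    return _CACHE
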
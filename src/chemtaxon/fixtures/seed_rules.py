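"""Seed classification rules bound to the seed taxonomy.

Each matchable rule carries positive and negative example structures; the
rule-set validator replays them all.  Weights follow non-hydrogen-atom
semantics: computed from the pattern for SMARTS rules, declared for
predicate rules as the heavy-atom count of the smallest compound the
constraints admit (the alkane rule declares 3 — propane — reflecting the
convention that the weight mirrors the smallest compound the category is
typically meant to capture rather than degenerate one- and two-carbon
members).

The thiazole rule uses the classic kekulé-style recursive SMARTS for the
1,3-thiazole ring; the alkane rule is the classic formula predicate
(RingCount = 0, CnH2n+2).  One preference pair is configured: "Flavonoid
glycosides" is selected over "Glycosides" when both apply, the standard
exception where the more informative composite term beats the often larger
plain saccharide feature.
"""

from __future__ import annotations

import yaml

from ..rules import RuleSet, parse_rule_file
from .seed_taxonomy import get_seed_taxonomy

__all__ = ["build_seed_ruleset", "get_seed_ruleset", "THIAZOLE_SMARTS", "ALKANE_PREDICATE"]

THIAZOLE_SMARTS = (
    "[$([#16]-1-[#6]=[#6]-[#6]=[#7]-1),$([#16]-1-[#6]=[#6]-[#7]=[#6]-1)]"
)

ALKANE_PREDICATE = (
    "RingCount() = 0 and AtomCount(C) > 0 "
    "and AtomCount(C) + AtomCount(H) = TotalAtomCount() "
    "and AtomCount(H) = 2 * AtomCount(C) + 2"
)

_STEROID_3OL = "[OX2H]C1CCC2(C)C3CCC4(C)CCCC4C3CCC2C1"
_STEROID_3OL_A = "[OX2H][C@@H]1CCC2(C)C3CCC4(C)CCCC4C3CCC2C1"
_STEROID_3OL_B = "[OX2H][C@H]1CCC2(C)C3CCC4(C)CCCC4C3CCC2C1"
_ANDROSTANOL = "OC1CCC2(C)C3CCC4(C)CCCC4C3CCC2C1"
_ANDROSTANOL_A = "O[C@@H]1CCC2(C)C3CCC4(C)CCCC4C3CCC2C1"
_ANDROSTANOL_B = "O[C@H]1CCC2(C)C3CCC4(C)CCCC4C3CCC2C1"

_FLAVONE = "O=C1C=C(Oc2ccccc21)c1ccccc1"
_FLAVONE_7_O_GLUCOSIDE = "OCC1OC(Oc2ccc3C(=O)C=C(Oc3c2)c2ccccc2)C(O)C(O)C1O"

# Rules keyed by taxonomy category *name*; ids are resolved at build time.
_R: list[dict] = [
    # ---- hydrocarbons
    dict(id="hydrocarbons", category="Hydrocarbons", kind="union"),
    dict(id="saturated-hydrocarbons", category="Saturated hydrocarbons", kind="union"),
    dict(id="alkanes", category="Alkanes", kind="predicate",
         expr=ALKANE_PREDICATE, weight=3,
         positive=["CCC", "CCCC", "CC(C)C", "CCCCCC"],
         negative=["C1CCCCC1", "C=C", "CCO"]),
    dict(id="cycloalkanes", category="Cycloalkanes", kind="predicate",
         expr=("RingCount() > 0 and AtomCount(C) > 0 "
               "and AtomCount(C) + AtomCount(H) = TotalAtomCount() "
               "and AtomCount(H) = 2 * AtomCount(C)"),
         weight=3, key=dict(cycles=1, ring_atoms=3),
         positive=["C1CCCCC1", "C1CCC1", "CC1CCCCC1"],
         negative=["CCCCCC", "C=CCC", "c1ccccc1"]),
    dict(id="alkenes", category="Alkenes", kind="predicate",
         expr=("RingCount() = 0 and AtomCount(C) > 0 "
               "and AtomCount(C) + AtomCount(H) = TotalAtomCount() "
               "and AtomCount(H) = 2 * AtomCount(C)"),
         weight=2,
         positive=["C=C", "CC=CC", "C=C(C)C"],
         negative=["CCCC", "C1CCCCC1", "C=CC=C"]),
    # ring closures also cost two hydrogens, so discount 2*RingCount() when
    # testing for double/triple-bond unsaturation by formula
    dict(id="unsaturated-hydrocarbons", category="Unsaturated hydrocarbons", kind="predicate",
         expr=("AtomCount(C) > 0 and AromaticRingCount() = 0 "
               "and AtomCount(C) + AtomCount(H) = TotalAtomCount() "
               "and AtomCount(H) + 2 * RingCount() < 2 * AtomCount(C) + 2"),
         weight=2,
         positive=["C=C", "C#C", "C=CC=C", "C1=CCCCC1"],
         negative=["CCCC", "C1CCCCC1", "c1ccccc1", "CCO"]),
    # ---- organoheterocyclic
    dict(id="organoheterocyclic", category="Organoheterocyclic compounds", kind="union"),
    dict(id="azoles", category="Azoles",
         patterns=["[n]1[c,n,o,s][c,n,o,s][c,n,o,s][c,n,o,s]1"],
         positive=["c1cscn1", "c1c[nH]cn1", "c1cc[nH]n1"],
         negative=["c1ccncc1", "c1ccoc1", "c1ccsc1"]),
    dict(id="thiazoles", category="Thiazoles", patterns=[THIAZOLE_SMARTS],
         positive=["c1cscn1", "Cc1nccs1", "Cc1csc(N)n1"],
         negative=["c1ccsc1", "c1ocnc1", "c1c[nH]cn1"]),
    dict(id="imidazoles", category="Imidazoles", patterns=["c1nccn1"],
         positive=["c1c[nH]cn1", "Cn1ccnc1"],
         negative=["c1cc[nH]n1", "c1cscn1"]),
    dict(id="pyrazoles", category="Pyrazoles", patterns=["c1ccnn1"],
         positive=["c1cc[nH]n1", "Cc1cc[nH]n1"],
         negative=["c1c[nH]cn1", "c1cscn1"]),
    dict(id="oxazoles", category="Oxazoles", patterns=["c1ncco1"],
         positive=["c1ocnc1", "Cc1ncco1"],
         negative=["c1ccoc1", "c1cscn1"]),
    dict(id="pyridines", category="Pyridines and derivatives", patterns=["c1ccncc1"],
         positive=["c1ccncc1", "Cc1ccccn1"],
         negative=["c1ccccc1", "c1cncnc1"]),
    dict(id="pyrimidines", category="Pyrimidines and derivatives", patterns=["c1cncnc1"],
         positive=["c1cncnc1", "Cc1ccncn1"],
         negative=["c1ccncc1", "c1ccccc1"]),
    dict(id="dioxanes", category="Dioxanes",
         patterns=["O1OCCCC1", "O1COCCC1", "O1CCOCC1"],
         positive=["O1OCCCC1", "O1CCOCC1", "O1COCCC1"],
         negative=["C1CCOC1", "O1CCCCC1"]),
    dict(id="12-dioxanes", category="1,2-Dioxanes", patterns=["O1OCCCC1"],
         positive=["O1OCCCC1"],
         negative=["O1CCOCC1", "O1COCCC1"]),
    dict(id="14-dioxanes", category="1,4-Dioxanes", patterns=["O1CCOCC1"],
         positive=["O1CCOCC1"],
         negative=["O1OCCCC1", "O1COCCC1"]),
    dict(id="furans", category="Furans", patterns=["c1ccoc1"],
         positive=["c1ccoc1", "Cc1ccco1"],
         negative=["c1ocnc1", "C1CCOC1"]),
    dict(id="thiophenes", category="Thiophenes", patterns=["c1ccsc1"],
         positive=["c1ccsc1", "Cc1cccs1"],
         negative=["c1cscn1", "C1CCSC1"]),
    # ---- benzenoids
    dict(id="benzenoids", category="Benzenoids", kind="union"),
    dict(id="benzene-derivatives", category="Benzene and substituted derivatives",
         patterns=["c1ccccc1"],
         positive=["c1ccccc1", "Cc1ccccc1", "CCc1ccccc1"],
         negative=["c1ccncc1", "C1CCCCC1"]),
    dict(id="benzoic-acids", category="Benzoic acids",
         patterns=["[OX2H1,OX1-][CX3](=[OX1])c1ccccc1"],
         positive=["OC(=O)c1ccccc1", "Cc1ccc(C(O)=O)cc1"],
         negative=["CC(O)=O", "OC(=O)Cc1ccccc1"]),
    dict(id="anilines", category="Anilines",
         patterns=["[NX3H2]c1ccccc1"],
         positive=["Nc1ccccc1", "Cc1ccc(N)cc1"],
         negative=["CNc1ccccc1", "NC1CCCCC1"]),
    dict(id="phenols", category="Phenols", patterns=["[OX2H]c1ccccc1"],
         positive=["Oc1ccccc1", "Cc1ccc(O)cc1"],
         negative=["OC1CCCCC1", "COc1ccccc1"]),
    dict(id="naphthalenes", category="Naphthalenes", patterns=["c1ccc2ccccc2c1"],
         positive=["c1ccc2ccccc2c1", "Cc1ccc2ccccc2c1"],
         negative=["c1ccccc1"]),
    # ---- organic acids
    dict(id="organic-acids", category="Organic acids and derivatives", kind="union"),
    dict(id="carboxylic-acid-derivatives", category="Carboxylic acids and derivatives",
         patterns=["[CX3](=[OX1])[OX2H1]", "[CX3](=[OX1])[OX1-]",
                   "[CX3](=[OX1])[OX2][#6]", "[CX3](=[OX1])[NX3]"],
         positive=["CC(O)=O", "COC(C)=O", "CC(N)=O"],
         negative=["CCO", "CC(C)=O"]),
    dict(id="carboxylic-acids", category="Carboxylic acids",
         patterns=["[CX3](=[OX1])[OX2H1]", "[CX3](=[OX1])[OX1-]"],
         substituent=True, substituent_name="carboxylic acid group",
         positive=["CC(O)=O", "OC=O", "CC(=O)[O-]"],
         negative=["COC(C)=O", "CC(C)=O"]),
    dict(id="carboxamides", category="Carboxamides",
         patterns=["[CX3](=[OX1])[NX3]"],
         substituent=True, substituent_name="carboxamide group",
         positive=["CC(N)=O", "CC(=O)NC"],
         negative=["CC(O)=O", "CN"]),
    dict(id="amino-acids-peptides", category="Amino acids, peptides, and analogues",
         kind="union"),
    dict(id="amino-acids", category="Amino acids",
         patterns=["[NX3H2,NX4H3+][CX4H1,CX4H2][CX3](=[OX1])[OX2H1,OX1-]"],
         positive=["NCC(O)=O", "CC(N)C(O)=O"],
         negative=["NCCC(O)=O", "NCC(=O)NCC(O)=O"]),
    dict(id="peptides", category="Peptides", kind="union"),
    dict(id="dipeptides", category="Dipeptides",
         patterns=["[NX3H2,NX4H3+][CX4H1,CX4H2][CX3](=[OX1])[NX3H1]"
                   "[CX4H1,CX4H2][CX3](=[OX1])[OX2H1,OX1-]"],
         positive=["NCC(=O)NCC(O)=O", "CC(N)C(=O)NCC(O)=O"],
         negative=["NCC(O)=O", "NCC(=O)NCC(=O)NCC(O)=O"]),
    dict(id="tripeptides", category="Tripeptides",
         patterns=["[NX3H2,NX4H3+][CX4H1,CX4H2][CX3](=[OX1])[NX3H1]"
                   "[CX4H1,CX4H2][CX3](=[OX1])[NX3H1]"
                   "[CX4H1,CX4H2][CX3](=[OX1])[OX2H1,OX1-]"],
         positive=["NCC(=O)NCC(=O)NCC(O)=O"],
         negative=["NCC(=O)NCC(O)=O"]),
    # ---- organic oxygen
    dict(id="organic-oxygen", category="Organic oxygen compounds", kind="union"),
    dict(id="organooxygen", category="Organooxygen compounds", patterns=["[#8]~[#6]"],
         positive=["CCO", "CC(C)=O", "c1ccoc1"],
         negative=["CCCC", "O", "CN"]),
    dict(id="alcohols", category="Alcohols and polyols", patterns=["[OX2H][CX4]"],
         substituent=True, substituent_name="hydroxyl group",
         positive=["CCO", "CC(C)O", "OCC(O)CO"],
         negative=["Oc1ccccc1", "CC(O)=O", "COC"]),
    dict(id="primary-alcohols", category="Primary alcohols", patterns=["[OX2H][CX4H2]"],
         substituent=True, substituent_name="primary alcohol",
         positive=["CCO", "CCCO", "OCC(O)CO"],
         negative=["CC(C)O", "CC(C)(C)O"]),
    dict(id="secondary-alcohols", category="Secondary alcohols", patterns=["[OX2H][CX4H1]"],
         substituent=True, substituent_name="secondary alcohol",
         positive=["CC(C)O", "CC(O)CC"],
         negative=["CCO", "CC(C)(C)O"]),
    dict(id="tertiary-alcohols", category="Tertiary alcohols",
         patterns=["[OX2H][CX4H0]([#6])([#6])[#6]"],
         substituent=True, substituent_name="tertiary alcohol",
         positive=["CC(C)(C)O", "CCC(C)(O)CC"],
         negative=["CCO", "CC(C)O"]),
    dict(id="carbonyl-compounds", category="Carbonyl compounds", patterns=["[CX3]=[OX1]"],
         substituent=True, substituent_name="carbonyl group",
         positive=["CC(C)=O", "CC=O", "CC(O)=O"],
         negative=["CCO", "COC"]),
    dict(id="ketones", category="Ketones", patterns=["[#6][CX3](=[OX1])[#6]"],
         substituent=True, substituent_name="ketone",
         positive=["CC(C)=O", "CCC(C)=O"],
         negative=["CC=O", "CC(O)=O"]),
    dict(id="aldehydes", category="Aldehydes", patterns=["[CX3H1](=[OX1])[#6]"],
         substituent=True, substituent_name="aldehyde group",
         positive=["CC=O", "CCC=O"],
         negative=["CC(C)=O", "CC(O)=O"]),
    dict(id="ethers", category="Ethers", patterns=["[OX2]([CX4])[CX4]"],
         substituent=True, substituent_name="ether",
         positive=["CCOCC", "COC", "C1CCOC1"],
         negative=["CCO", "COC(C)=O", "c1ccoc1"]),
    dict(id="glycosides", category="Glycosides",
         patterns=["[CX4H1]1([OX2][#6])[OX2][CX4][CX4][CX4][CX4]1"],
         positive=["COC1OC(CO)C(O)C(O)C1O", _FLAVONE_7_O_GLUCOSIDE],
         negative=["OCC1OC(O)C(O)C(O)C1O", "C1CCOC1"]),
    # ---- organic nitrogen
    dict(id="organic-nitrogen", category="Organic nitrogen compounds", kind="union"),
    dict(id="organonitrogen", category="Organonitrogen compounds", patterns=["[#7]~[#6]"],
         positive=["CN", "CC#N", "c1ccncc1"],
         negative=["CCO", "N", "O"]),
    dict(id="amines", category="Amines",
         patterns=["[NX3;!$([NX3][#6X3]=[O,S,N]);!$([NX3][!#6;!#1])][#6]"],
         positive=["CN", "CNC", "CN(C)C", "Nc1ccccc1"],
         negative=["CC(N)=O", "c1ccncc1"]),
    dict(id="primary-amines", category="Primary amines",
         patterns=["[NX3H2;!$([NX3][#6X3]=[O,S,N]);!$([NX3][!#6;!#1])][#6]"],
         substituent=True, substituent_name="primary amine",
         positive=["CN", "NCCO", "Nc1ccccc1"],
         negative=["CNC", "CC(N)=O"]),
    dict(id="secondary-amines", category="Secondary amines",
         patterns=["[NX3H1;!$([NX3][#6X3]=[O,S,N]);!$([NX3][!#6;!#1])]([#6])[#6]"],
         substituent=True, substituent_name="secondary amine",
         positive=["CNC", "CCNC"],
         negative=["CN", "CN(C)C", "CC(=O)NC"]),
    dict(id="tertiary-amines", category="Tertiary amines",
         patterns=["[NX3H0;!$([NX3][#6X3]=[O,S,N]);!$([NX3][!#6;!#1])]([#6])([#6])[#6]"],
         substituent=True, substituent_name="tertiary amine",
         positive=["CN(C)C", "CCN(CC)CC"],
         negative=["CNC", "CN(C)C(C)=O"]),
    # ---- organosulfur / organohalogen
    dict(id="organosulfur", category="Organosulfur compounds", patterns=["[#16]~[#6]"],
         positive=["CS", "CSC", "c1ccsc1"],
         negative=["CCO", "S", "O=S(=O)(O)O"]),
    dict(id="thiols", category="Thiols", patterns=["[SX2H][#6]"],
         substituent=True, substituent_name="thiol group",
         positive=["CS", "CCS"],
         negative=["CSC", "S"]),
    dict(id="organohalogens", category="Organohalogen compounds",
         patterns=["[F,Cl,Br,I][#6]"],
         substituent=True, substituent_name="halogen atom",
         positive=["CCl", "CF", "Clc1ccccc1"],
         negative=["CC", "[Na+].[Cl-]"]),
    dict(id="organochlorides", category="Organochlorides", patterns=["[Cl][#6]"],
         positive=["CCl", "ClCCCl", "Clc1ccccc1"],
         negative=["CF", "[Na+].[Cl-]"]),
    dict(id="organofluorides", category="Organofluorides", patterns=["[F][#6]"],
         positive=["CF", "FC(F)(F)F"],
         negative=["CCl", "CC"]),
    # ---- lipids
    dict(id="lipids", category="Lipids and lipid-like molecules", kind="union"),
    dict(id="steroids", category="Steroids and steroid derivatives",
         patterns=["C1CCC2(C)C3CCC4(C)CCCC4C3CCC2C1"],
         positive=["C1CCC2(C)C3CCC4(C)CCCC4C3CCC2C1", _ANDROSTANOL],
         negative=["C1CCCCC1", "c1ccc2ccccc2c1"]),
    dict(id="hydroxysteroids", category="Hydroxysteroids", kind="union"),
    dict(id="3-hydroxysteroids", category="3-hydroxysteroids", patterns=[_STEROID_3OL],
         positive=[_ANDROSTANOL, _ANDROSTANOL_A, _ANDROSTANOL_B],
         negative=["CC12CCCCC1CCC1C2CCC2(C)C1CCC2", "OC1CCCCC1"]),
    dict(id="3-alpha-hydroxysteroids", category="3-alpha-hydroxysteroids",
         patterns=[_STEROID_3OL_A], stereo=True,
         positive=[_ANDROSTANOL_A],
         negative=[_ANDROSTANOL_B, _ANDROSTANOL]),
    dict(id="3-beta-hydroxysteroids", category="3-beta-hydroxysteroids",
         patterns=[_STEROID_3OL_B], stereo=True,
         positive=[_ANDROSTANOL_B],
         negative=[_ANDROSTANOL_A, _ANDROSTANOL]),
    dict(id="fatty-acyls", category="Fatty acyls", kind="union"),
    dict(id="fatty-acids", category="Fatty acids and conjugates",
         patterns=["[CX4][CX4][CX4][CX4][CX4][CX3](=[OX1])[OX2H1,OX1-]"],
         positive=["CCCCCC(O)=O", "CCCCCCCC(O)=O"],
         negative=["CC(O)=O", "CCCC(O)=O"]),
    # ---- phenylpropanoids and polyketides
    dict(id="phenylpropanoids", category="Phenylpropanoids and polyketides", kind="union"),
    dict(id="flavonoids", category="Flavonoids", kind="union"),
    dict(id="flavones", category="Flavones",
         patterns=["[OX1]=c1cc(-c2ccccc2)oc2ccccc12",
                   "[OX1]=[#6]1[#6]=[#6](-[#6]2[#6]=[#6][#6]=[#6][#6]=2)"
                   "[#8][#6]2[#6]=[#6][#6]=[#6][#6]=12"],
         positive=[_FLAVONE, _FLAVONE_7_O_GLUCOSIDE],
         negative=["c1ccccc1", "O=C1CCOc2ccccc21"]),
    dict(id="flavonoid-glycosides", category="Flavonoid glycosides",
         patterns=["[OX1]=c1cc(-c2ccccc2)oc2cc([OX2][CX4H1]3[OX2][CX4][CX4][CX4][CX4]3)ccc12"],
         positive=[_FLAVONE_7_O_GLUCOSIDE],
         negative=[_FLAVONE, "COC1OC(CO)C(O)C(O)C1O"]),
    # ---- salts
    dict(id="organic-salts", category="Organic salts", kind="union"),
    dict(id="organic-chlorine-salts", category="Organic chlorine salts",
         patterns=["[#6].[Cl;X0;-]"], scope="mixture",
         positive=["C[NH3+].[Cl-]", "CC(=O)[O-].[Na+].[Cl-]"],
         negative=["CCl"]),
    # ---- inorganic
    dict(id="homogeneous-metal", category="Homogeneous metal compounds", kind="union"),
    dict(id="alkali-metal-compounds", category="Homogeneous alkali metal compounds",
         patterns=["[Li,Na,K,Rb,Cs]"],
         positive=["[Na+]", "[K+]", "[Na+].[Cl-]"],
         negative=["[Fe]", "O"]),
    dict(id="transition-metal-compounds", category="Homogeneous transition metal compounds",
         patterns=["[Sc,Ti,V,Cr,Mn,Fe,Co,Ni,Cu,Zn]"],
         positive=["[Fe]", "[Cu+2]"],
         negative=["[Na+]", "O"]),
    dict(id="homogeneous-nonmetal", category="Homogeneous non-metal compounds", kind="union"),
    dict(id="nonmetal-oxides", category="Non-metal oxides",
         patterns=["[OX1]=[#6,#7,#14,#15,#16]"],
         positive=["O=C=O", "O=S=O", "O=[N+]([O-])O"],
         negative=["O", "[Na+].[Cl-]"]),
    dict(id="homogeneous-halogens", category="Homogeneous halogens",
         patterns=["[F,Cl,Br,I;X0]"],
         positive=["[Cl-]", "[F-]", "[Na+].[Cl-]"],
         negative=["CCl", "ClCl"]),
    dict(id="inorganic-salts", category="Inorganic salts", kind="union"),
    dict(id="alkali-metal-salts", category="Alkali metal salts",
         patterns=["[Li+,Na+,K+,Rb+,Cs+].[F-,Cl-,Br-,I-]"], scope="mixture",
         positive=["[Na+].[Cl-]", "[K+].[Br-]"],
         negative=["C[NH3+].[Cl-]"]),
]


def build_seed_ruleset() -> str:
    """Resolve category names to seed-taxonomy ids and emit the YAML text."""
    tax = get_seed_taxonomy()
    entries = []
    for spec in _R:
        entry = dict(spec)
        entry["category"] = tax.find_by_name(entry["category"]).id
        entries.append(entry)
    doc = {
        "rules": entries,
        "preferences": [
            {
                "prefer": tax.find_by_name("Flavonoid glycosides").id,
                "over": tax.find_by_name("Glycosides").id,
            }
        ],
    }
    return yaml.safe_dump(doc, sort_keys=False, width=1000)


_CACHE: RuleSet | None = None


def get_seed_ruleset() -> RuleSet:
    """Parsed and compiled seed rule set (cached)."""
    global _CACHE
    if _CACHE is None:
        _CACHE = parse_rule_file(build_seed_ruleset(), get_seed_taxonomy())
    return _CACHE
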
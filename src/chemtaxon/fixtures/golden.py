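"""Golden classification corpus: molecules with hand-derived expectations.

Each entry records the outcome a curator derives by reading the seed rule
definitions and taxonomy — which rules match, what survives antichain
reduction, which candidate carries the largest feature weight — without
running the classifier.  The full pipeline must reproduce every entry.

Category references are by name (resolved against the seed taxonomy);
``alternative_parents`` is the complete expected set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["GoldenEntry", "build_golden_corpus"]

ORGANIC = "Organic compounds"
INORGANIC = "Inorganic compounds"
ACYCLIC = "aliphatic acyclic compound"
AL_MONO = "aliphatic homomonocyclic compound"
AL_HET = "aliphatic heteromonocyclic compound"
AL_POLY = "aliphatic homopolycyclic compound"
AR_MONO = "aromatic homomonocyclic compound"
AR_HET = "aromatic heteromonocyclic compound"
AR_POLY = "aromatic homopolycyclic compound"
AR_HETPOLY = "aromatic heteropolycyclic compound"


@dataclass(frozen=True)
class GoldenEntry:
    rid: str
    smiles: str
    kingdom: str
    direct_parent: str
    alternative_parents: tuple[str, ...] = ()
    framework: str | None = None
    shallow: bool = False
    mixture: bool = False


_STEROL = "OC1CCC2(C)C3CCC4(C)CCCC4C3CCC2C1"

_CORPUS: list[GoldenEntry] = [
    # ---- alkanes: CnH2n+2, no rings; nothing else fires
    GoldenEntry("methane", "C", ORGANIC, "Alkanes", (), ACYCLIC),
    GoldenEntry("ethane", "CC", ORGANIC, "Alkanes", (), ACYCLIC),
    GoldenEntry("propane", "CCC", ORGANIC, "Alkanes", (), ACYCLIC),
    GoldenEntry("butane", "CCCC", ORGANIC, "Alkanes", (), ACYCLIC),
    GoldenEntry("isobutane", "CC(C)C", ORGANIC, "Alkanes", (), ACYCLIC),
    GoldenEntry("pentane", "CCCCC", ORGANIC, "Alkanes", (), ACYCLIC),
    GoldenEntry("neopentane", "CC(C)(C)C", ORGANIC, "Alkanes", (), ACYCLIC),
    GoldenEntry("hexane", "CCCCCC", ORGANIC, "Alkanes", (), ACYCLIC),
    GoldenEntry("octane", "CCCCCCCC", ORGANIC, "Alkanes", (), ACYCLIC),
    # ---- cycloalkanes: CnH2n with a ring
    GoldenEntry("cyclopentane", "C1CCCC1", ORGANIC, "Cycloalkanes", (), AL_MONO),
    GoldenEntry("cyclohexane", "C1CCCCC1", ORGANIC, "Cycloalkanes", (), AL_MONO),
    GoldenEntry("methylcyclohexane", "CC1CCCCC1", ORGANIC, "Cycloalkanes", (), AL_MONO),
    # ---- unsaturated hydrocarbons; the mono-ene formula isolates alkenes
    GoldenEntry("ethene", "C=C", ORGANIC, "Alkenes", (), ACYCLIC),
    GoldenEntry("2-butene", "CC=CC", ORGANIC, "Alkenes", (), ACYCLIC),
    GoldenEntry("isobutylene", "C=C(C)C", ORGANIC, "Alkenes", (), ACYCLIC),
    GoldenEntry("butadiene", "C=CC=C", ORGANIC, "Unsaturated hydrocarbons", (), ACYCLIC),
    GoldenEntry("acetylene", "C#C", ORGANIC, "Unsaturated hydrocarbons", (), ACYCLIC),
    GoldenEntry("cyclohexene", "C1=CCCCC1", ORGANIC, "Unsaturated hydrocarbons", (), AL_MONO),
    # ---- benzenoids
    GoldenEntry("benzene", "c1ccccc1", ORGANIC, "Benzene and substituted derivatives", (), AR_MONO),
    GoldenEntry("toluene", "Cc1ccccc1", ORGANIC, "Benzene and substituted derivatives", (), AR_MONO),
    GoldenEntry("ethylbenzene", "CCc1ccccc1", ORGANIC, "Benzene and substituted derivatives", (), AR_MONO),
    GoldenEntry("naphthalene", "c1ccc2ccccc2c1", ORGANIC, "Naphthalenes",
                ("Benzene and substituted derivatives",), AR_POLY),
    GoldenEntry("phenol", "Oc1ccccc1", ORGANIC, "Phenols",
                ("Benzene and substituted derivatives", "Organooxygen compounds"), AR_MONO),
    GoldenEntry("p-cresol", "Cc1ccc(O)cc1", ORGANIC, "Phenols",
                ("Benzene and substituted derivatives", "Organooxygen compounds"), AR_MONO),
    GoldenEntry("chlorobenzene", "Clc1ccccc1", ORGANIC, "Benzene and substituted derivatives",
                ("Organochlorides",), AR_MONO),
    # ---- alcohols and ethers
    GoldenEntry("ethanol", "CCO", ORGANIC, "Primary alcohols", (), ACYCLIC),
    GoldenEntry("1-propanol", "CCCO", ORGANIC, "Primary alcohols", (), ACYCLIC),
    GoldenEntry("1-butanol", "CCCCO", ORGANIC, "Primary alcohols", (), ACYCLIC),
    GoldenEntry("isopropanol", "CC(C)O", ORGANIC, "Secondary alcohols", (), ACYCLIC),
    GoldenEntry("2-butanol", "CCC(C)O", ORGANIC, "Secondary alcohols", (), ACYCLIC),
    GoldenEntry("tert-butanol", "CC(C)(C)O", ORGANIC, "Tertiary alcohols", (), ACYCLIC),
    GoldenEntry("diethyl-ether", "CCOCC", ORGANIC, "Ethers", (), ACYCLIC),
    GoldenEntry("thf", "C1CCOC1", ORGANIC, "Ethers", (), AL_HET),
    # ---- carbonyls
    GoldenEntry("acetone", "CC(C)=O", ORGANIC, "Ketones", (), ACYCLIC),
    GoldenEntry("2-butanone", "CCC(C)=O", ORGANIC, "Ketones", (), ACYCLIC),
    GoldenEntry("acetaldehyde", "CC=O", ORGANIC, "Aldehydes", (), ACYCLIC),
    GoldenEntry("propanal", "CCC=O", ORGANIC, "Aldehydes", (), ACYCLIC),
    # ---- acids and derivatives
    GoldenEntry("formic-acid", "OC=O", ORGANIC, "Carboxylic acids",
                ("Carbonyl compounds",), ACYCLIC),
    GoldenEntry("acetic-acid", "CC(O)=O", ORGANIC, "Carboxylic acids",
                ("Carbonyl compounds",), ACYCLIC),
    GoldenEntry("benzoic-acid", "OC(=O)c1ccccc1", ORGANIC, "Benzoic acids",
                ("Carboxylic acids", "Carbonyl compounds"), AR_MONO),
    GoldenEntry("octanoic-acid", "CCCCCCCC(O)=O", ORGANIC, "Fatty acids and conjugates",
                ("Carboxylic acids", "Carbonyl compounds"), ACYCLIC),
    # amides are excluded from the amine subtree, so the generic
    # organonitrogen category survives reduction as an alternative parent
    GoldenEntry("acetamide", "CC(N)=O", ORGANIC, "Carboxamides",
                ("Carbonyl compounds", "Organonitrogen compounds"), ACYCLIC),
    GoldenEntry("n-methylacetamide", "CC(=O)NC", ORGANIC, "Carboxamides",
                ("Carbonyl compounds", "Organonitrogen compounds"), ACYCLIC),
    # ---- amines
    GoldenEntry("methylamine", "CN", ORGANIC, "Primary amines", (), ACYCLIC),
    GoldenEntry("dimethylamine", "CNC", ORGANIC, "Secondary amines", (), ACYCLIC),
    GoldenEntry("trimethylamine", "CN(C)C", ORGANIC, "Tertiary amines", (), ACYCLIC),
    GoldenEntry("aniline", "Nc1ccccc1", ORGANIC, "Anilines", ("Primary amines",), AR_MONO),
    # primary alcohol and primary amine tie at weight 2 with identical
    # (all-zero) structural keys, so the ascending-id fallback decides:
    # the alcohol's low seed-assigned id sorts before amine id 0002450
    GoldenEntry("ethanolamine", "NCCO", ORGANIC, "Primary alcohols",
                ("Primary amines",), ACYCLIC),
    # ---- amino acids and peptides
    GoldenEntry("glycine", "NCC(O)=O", ORGANIC, "Amino acids",
                ("Carboxylic acids", "Carbonyl compounds", "Primary amines"), ACYCLIC),
    GoldenEntry("alanine", "CC(N)C(O)=O", ORGANIC, "Amino acids",
                ("Carboxylic acids", "Carbonyl compounds", "Primary amines"), ACYCLIC),
    GoldenEntry("glycylglycine", "NCC(=O)NCC(O)=O", ORGANIC, "Dipeptides",
                ("Carboxylic acids", "Carboxamides", "Carbonyl compounds", "Primary amines"),
                ACYCLIC),
    GoldenEntry("alanylglycine", "CC(N)C(=O)NCC(O)=O", ORGANIC, "Dipeptides",
                ("Carboxylic acids", "Carboxamides", "Carbonyl compounds", "Primary amines"),
                ACYCLIC),
    GoldenEntry("triglycine", "NCC(=O)NCC(=O)NCC(O)=O", ORGANIC, "Tripeptides",
                ("Carboxylic acids", "Carboxamides", "Carbonyl compounds", "Primary amines"),
                ACYCLIC),
    # ---- azoles and other heterocycles
    GoldenEntry("thiazole", "c1cscn1", ORGANIC, "Thiazoles",
                ("Organonitrogen compounds", "Organosulfur compounds"), AR_HET),
    GoldenEntry("2-methylthiazole", "Cc1nccs1", ORGANIC, "Thiazoles",
                ("Organonitrogen compounds", "Organosulfur compounds"), AR_HET),
    GoldenEntry("imidazole", "c1c[nH]cn1", ORGANIC, "Imidazoles",
                ("Organonitrogen compounds",), AR_HET),
    GoldenEntry("1-methylimidazole", "Cn1ccnc1", ORGANIC, "Imidazoles",
                ("Organonitrogen compounds",), AR_HET),
    GoldenEntry("pyrazole", "c1cc[nH]n1", ORGANIC, "Pyrazoles",
                ("Organonitrogen compounds",), AR_HET),
    GoldenEntry("oxazole", "c1ocnc1", ORGANIC, "Oxazoles",
                ("Organonitrogen compounds", "Organooxygen compounds"), AR_HET),
    GoldenEntry("pyridine", "c1ccncc1", ORGANIC, "Pyridines and derivatives",
                ("Organonitrogen compounds",), AR_HET),
    GoldenEntry("2-methylpyridine", "Cc1ccccn1", ORGANIC, "Pyridines and derivatives",
                ("Organonitrogen compounds",), AR_HET),
    GoldenEntry("pyrimidine", "c1cncnc1", ORGANIC, "Pyrimidines and derivatives",
                ("Organonitrogen compounds",), AR_HET),
    GoldenEntry("furan", "c1ccoc1", ORGANIC, "Furans", ("Organooxygen compounds",), AR_HET),
    GoldenEntry("2-methylfuran", "Cc1ccco1", ORGANIC, "Furans",
                ("Organooxygen compounds",), AR_HET),
    GoldenEntry("thiophene", "c1ccsc1", ORGANIC, "Thiophenes",
                ("Organosulfur compounds",), AR_HET),
    GoldenEntry("1,4-dioxane", "O1CCOCC1", ORGANIC, "1,4-Dioxanes", ("Ethers",), AL_HET),
    GoldenEntry("1,2-dioxane", "O1OCCCC1", ORGANIC, "1,2-Dioxanes",
                ("Organooxygen compounds",), AL_HET),
    # ---- organohalogens / organosulfur
    GoldenEntry("chloromethane", "CCl", ORGANIC, "Organochlorides", (), ACYCLIC),
    GoldenEntry("dichloromethane", "ClCCl", ORGANIC, "Organochlorides", (), ACYCLIC),
    GoldenEntry("fluoromethane", "CF", ORGANIC, "Organofluorides", (), ACYCLIC),
    GoldenEntry("ethanethiol", "CCS", ORGANIC, "Thiols", (), ACYCLIC),
    # ---- carbohydrates and flavonoids
    GoldenEntry("methyl-glucoside", "COC1OC(CO)C(O)C(O)C1O", ORGANIC, "Glycosides",
                ("Ethers", "Primary alcohols", "Secondary alcohols"), AL_HET),
    GoldenEntry("flavone", "O=C1C=C(Oc2ccccc21)c1ccccc1", ORGANIC, "Flavones",
                ("Benzene and substituted derivatives", "Ketones"), AR_HETPOLY),
    GoldenEntry("flavone-7-O-glucoside",
                "OCC1OC(Oc2ccc3C(=O)C=C(Oc3c2)c2ccccc2)C(O)C(O)C1O",
                ORGANIC, "Flavonoid glycosides",
                ("Benzene and substituted derivatives", "Ethers", "Flavones",
                 "Glycosides", "Ketones", "Primary alcohols", "Secondary alcohols"),
                AR_HETPOLY),
    # ---- steroids (stereo-specific rules need stereo-annotated input)
    GoldenEntry("androstanol-flat", _STEROL, ORGANIC, "3-hydroxysteroids",
                ("Secondary alcohols",), AL_POLY),
    GoldenEntry("androstanol-3a", "O[C@@H]1CCC2(C)C3CCC4(C)CCCC4C3CCC2C1",
                ORGANIC, "3-alpha-hydroxysteroids", ("Secondary alcohols",), AL_POLY),
    GoldenEntry("androstanol-3b", "O[C@H]1CCC2(C)C3CCC4(C)CCCC4C3CCC2C1",
                ORGANIC, "3-beta-hydroxysteroids", ("Secondary alcohols",), AL_POLY),
    # ---- inorganic kingdom, incl. the carbon-containing exceptions
    GoldenEntry("carbon-dioxide", "O=C=O", INORGANIC, "Non-metal oxides", (), ACYCLIC),
    GoldenEntry("carbon-monoxide", "[C-]#[O+]", INORGANIC, INORGANIC, (), ACYCLIC, shallow=True),
    GoldenEntry("carbon-disulfide", "S=C=S", INORGANIC, INORGANIC, (), ACYCLIC, shallow=True),
    GoldenEntry("hydrogen-cyanide", "C#N", INORGANIC, INORGANIC, (), ACYCLIC, shallow=True),
    GoldenEntry("water", "O", INORGANIC, INORGANIC, (), ACYCLIC, shallow=True),
    GoldenEntry("sodium-cation", "[Na+]", INORGANIC, "Homogeneous alkali metal compounds",
                (), ACYCLIC),
    GoldenEntry("iron", "[Fe]", INORGANIC, "Homogeneous transition metal compounds",
                (), ACYCLIC),
    GoldenEntry("chloride", "[Cl-]", INORGANIC, "Homogeneous halogens", (), ACYCLIC),
    # ---- mixtures
    GoldenEntry("sodium-chloride", "[Na+].[Cl-]", INORGANIC, "Alkali metal salts",
                ("Homogeneous alkali metal compounds", "Homogeneous halogens"),
                None, mixture=True),
    GoldenEntry("potassium-bromide", "[K+].[Br-]", INORGANIC, "Alkali metal salts",
                ("Homogeneous alkali metal compounds", "Homogeneous halogens"),
                None, mixture=True),
    GoldenEntry("methylammonium-chloride", "C[NH3+].[Cl-]", ORGANIC,
                "Organic chlorine salts", ("Organonitrogen compounds",),
                None, mixture=True),
]


def build_golden_corpus() -> list[GoldenEntry]:
    """The corpus as data (names resolved against the seed taxonomy by the
    consumer); deterministic and self-contained."""
    return list(_CORPUS)
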
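"""Deterministic synthetic-molecule generators for tests and demos.

All generators are pure functions of a :class:`GeneratorConfig`: the same
seed and bounds always produce the same SMILES lists, bit for bit.
"""

from __future__ import annotations

import random
import zlib
from dataclasses import dataclass

from rdkit import Chem

__all__ = ["GeneratorConfig", "SCAFFOLDS", "SUBSTITUENTS", "gen_alkanes", "gen_decorated"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Seed and size bounds shared by all generators."""

    seed: int = 42
    count: int = 10          # molecules per family
    min_carbons: int = 1
    max_carbons: int = 8


def gen_alkanes(config: GeneratorConfig = GeneratorConfig()) -> list[str]:
    """Unbranched alkanes over the carbon range plus randomly branched ones.

    Every output is a tree of carbon atoms, hence CnH2n+2 by construction.
    """
    if config.min_carbons < 1:
        raise ValueError("carbon range must start at 1 or more")
    out = ["C" * n for n in range(config.min_carbons, config.max_carbons + 1)]
    rng = random.Random(config.seed)
    seen = set(out)
    attempts = 0
    while len(out) < config.count + (config.max_carbons - config.min_carbons + 1) and attempts < 200:
        attempts += 1
        n = rng.randint(max(4, config.min_carbons), config.max_carbons)
        mol = Chem.RWMol()
        mol.AddAtom(Chem.Atom(6))
        for _ in range(n - 1):
            candidates = [
                a.GetIdx() for a in mol.GetAtoms() if a.GetDegree() < 4
            ]
            parent = rng.choice(candidates)
            idx = mol.AddAtom(Chem.Atom(6))
            mol.AddBond(parent, idx, Chem.BondType.SINGLE)
        smiles = Chem.MolToSmiles(mol.GetMol())
        if smiles not in seen:
            seen.add(smiles)
            out.append(smiles)
    return out


# Scaffold templates by substituent count (0-3); slots are filled textually,
# so substituent fragments must be written to extend a SMILES string.
SCAFFOLDS: dict[str, list[str]] = {
    "benzene": [
        "c1ccccc1",
        "{0}c1ccccc1",
        "c1cc({0})ccc1{1}",
        "c1c({2})cc({0})cc1{1}",
    ],
    "thiazole": [
        "c1cscn1",
        "{0}c1nccs1",
        "{0}c1ncc({1})s1",
        "{0}c1nc({2})c({1})s1",
    ],
    "pyridine": [
        "c1ccncc1",
        "{0}c1ccccn1",
        "{0}c1cc({1})ccn1",
        "{0}c1cc({2})c({1})cn1",
    ],
    "glucose": [
        "OCC1OC(O)C(O)C(O)C1O",
        "OCC1OC(O{0})C(O)C(O)C1O",
        "OCC1OC(O{0})C(O)C(O{1})C1O",
        "OCC1OC(O{0})C(O{2})C(O{1})C1O",
    ],
    "flavone": [
        "O=C1C=C(Oc2ccccc21)c1ccccc1",
        "O=C1C=C(Oc2cc({0})ccc21)c1ccccc1",
        "O=C1C=C(Oc2cc({0})ccc21)c1ccc({1})cc1",
        "O=C1C=C(Oc2cc({0})cc({2})c21)c1ccc({1})cc1",
    ],
}

# Fragments written for textual attachment; ring closures use digit 9 to
# avoid clashing with scaffold ring numbering.
SUBSTITUENTS: dict[str, str] = {
    "methyl": "C",
    "ethyl": "CC",
    "hydroxyl": "O",
    "chloro": "Cl",
    "glucosyl": "OC9OC(CO)C(O)C(O)C9O",  # O-linked: attachment forms a glycosidic bond
}


def gen_decorated(
    scaffold: str,
    substituents: list[str] | None = None,
    config: GeneratorConfig = GeneratorConfig(),
) -> list[str]:
    """Scaffold with 0–3 substituents at chemically valid positions.

    ``substituents`` are names from :data:`SUBSTITUENTS`.  The first output
    is always the bare scaffold; the rest are drawn deterministically from
    the configured seed.  Every output is checked to parse.
    """
    if scaffold not in SCAFFOLDS:
        raise ValueError(
            f"unknown scaffold {scaffold!r}; available: {sorted(SCAFFOLDS)}"
        )
    names = substituents if substituents is not None else ["methyl", "ethyl", "chloro"]
    for name in names:
        if name not in SUBSTITUENTS:
            raise ValueError(f"unknown substituent {name!r}")
    templates = SCAFFOLDS[scaffold]
    # str hashes are salted per process; derive a stable stream id instead
    rng = random.Random(config.seed ^ zlib.crc32(scaffold.encode()))
    out = [templates[0]]
    seen = {Chem.CanonSmiles(templates[0])}
    attempts = 0
    while len(out) < config.count and attempts < 200:
        attempts += 1
        k = rng.randint(1, min(3, len(templates) - 1))
        frags = [SUBSTITUENTS[rng.choice(names)] for _ in range(k)]
        smiles = templates[k].format(*frags)
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:  # pragma: no cover - templates are valid by design
            continue
        canon = Chem.MolToSmiles(mol)
        if canon not in seen:
            seen.add(canon)
            out.append(smiles)
    return out
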
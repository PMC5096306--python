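"""Molecule ingestion and standardization (step 1 of the pipeline).

Input structures (SMILES, InChI, or an MDL molfile record) are parsed,
functional groups are normalized (e.g. both nitro drawings collapse to the
charge-separated form), the molecule is aromatized under the toolkit's
default aromaticity model, and disconnected fragments are split into
components ordered deterministically (descending heavy-atom count, ties by
canonical SMILES).  Net charges are preserved; stereo annotations are kept
as given.  Standardization is idempotent: running it on its own output is a
no-op.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize
from rdkit.Chem.rdMolDescriptors import CalcNumAromaticRings, CalcNumRings

RDLogger.DisableLog("rdApp.*")

__all__ = ["StandardizedMolecule", "StructureError", "preprocess"]

INPUT_FORMATS = ("smiles", "inchi", "sdf")


class StructureError(ValueError):
    """Unparseable or empty chemical input."""


_NORMALIZER = rdMolStandardize.Normalizer()


def _formula_counts(mol: Chem.Mol) -> dict[str, int]:
    counts: dict[str, int] = {}
    h = 0
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        counts[sym] = counts.get(sym, 0) + 1
        h += atom.GetTotalNumHs()
    if h:
        counts["H"] = counts.get("H", 0) + h
    return counts


@dataclass
class StandardizedMolecule:
    """A parsed, normalized, aromatized structure plus computed properties.

    ``components`` lists each disconnected fragment as its own
    :class:`StandardizedMolecule` (a single-fragment molecule lists itself
    once).  ``formula`` includes implicit hydrogens.
    """

    mol: Chem.Mol
    canonical_smiles: str
    formula: dict[str, int]
    ring_count: int
    aromatic_ring_count: int
    heavy_atom_count: int
    components: list["StandardizedMolecule"] = field(default_factory=list)

    @property
    def is_mixture(self) -> bool:
        return len(self.components) > 1

    @property
    def carbon_count(self) -> int:
        return self.formula.get("C", 0)

    def kekulized(self) -> Chem.Mol:
        """A kekulized copy with aromatic flags cleared, for patterns written
        against alternating single/double bonds."""
        mol = Chem.Mol(self.mol)
        Chem.Kekulize(mol, clearAromaticFlags=True)
        return mol


def _standardize_mol(mol: Chem.Mol) -> Chem.Mol:
    mol = _NORMALIZER.normalize(mol)
    Chem.SanitizeMol(mol)
    Chem.SetAromaticity(mol)
    return mol


def _wrap(mol: Chem.Mol, components: list[StandardizedMolecule] | None = None) -> StandardizedMolecule:
    sm = StandardizedMolecule(
        mol=mol,
        canonical_smiles=Chem.MolToSmiles(mol),
        formula=_formula_counts(mol),
        ring_count=CalcNumRings(mol),
        aromatic_ring_count=CalcNumAromaticRings(mol),
        heavy_atom_count=mol.GetNumHeavyAtoms(),
    )
    sm.components = components if components is not None else [sm]
    return sm


def _parse(text: str, fmt: str) -> Chem.Mol:
    if fmt == "smiles":
        mol = Chem.MolFromSmiles(text)
    elif fmt == "inchi":
        mol = Chem.MolFromInchi(text)
    elif fmt == "sdf":
        mol = Chem.MolFromMolBlock(text)
    else:
        raise StructureError(f"unknown input format {fmt!r} (expected one of {INPUT_FORMATS})")
    if mol is None:
        raise StructureError(f"unparseable {fmt} input: {text.strip()[:80]!r}")
    if mol.GetNumAtoms() == 0:
        raise StructureError("empty structure")
    return mol


def preprocess(text: str, fmt: str = "smiles") -> StandardizedMolecule:
    """Parse and standardize one input record.

    Returns the standardized molecule; for a disconnected input its
    ``components`` hold each fragment standardized separately, sorted by
    descending heavy-atom count (ties by canonical SMILES).
    """
    mol = _standardize_mol(_parse(text, fmt))
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if len(frags) == 1:
        return _wrap(mol)
    comps = [_wrap(_standardize_mol(f)) for f in frags]
    comps.sort(key=lambda c: (-c.heavy_atom_count, c.canonical_smiles))
    whole = _wrap(mol, components=comps)
    return whole
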
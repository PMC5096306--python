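"""Readers and writers for standard chemistry formats plus the peptide adapter.

Readers stream records and never abort on a single bad record (unless
``strict``): malformed entries come back as error records so batch runs can
report per-record failures.  Writers are deterministic: the same results
produce byte-identical output.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from pydantic import BaseModel, Field
from rdkit import Chem

from .classify import ClassificationResult

__all__ = [
    "InputRecord",
    "ReadError",
    "peptide_to_structure",
    "read_structures",
    "result_to_dict",
    "write_results",
]


class ReadError(ValueError):
    pass


@dataclass(frozen=True)
class InputRecord:
    record_id: str
    text: str
    fmt: str
    error: str | None = None


# -- peptide adapter -----------------------------------------------------------

# Side-chain SMILES fragments for the 20 standard residues, attached to an
# L-configured alpha carbon ("N[C@@H](side)C(=O)"); glycine is achiral and
# proline contributes its own ring.
_SIDE_CHAINS: dict[str, str] = {
    "A": "C",
    "R": "CCCNC(=N)N",
    "N": "CC(N)=O",
    "D": "CC(O)=O",
    "C": "CS",
    "E": "CCC(O)=O",
    "Q": "CCC(N)=O",
    "H": "Cc1c[nH]cn1",
    "I": "C(C)CC",
    "L": "CC(C)C",
    "K": "CCCCN",
    "M": "CCSC",
    "F": "Cc1ccccc1",
    "S": "CO",
    "T": "C(C)O",
    "W": "Cc1c[nH]c2ccccc12",
    "Y": "Cc1ccc(O)cc1",
    "V": "C(C)C",
}
_NUCLEOTIDE_LETTERS = set("ACGTUN")


def peptide_to_structure(sequence: str) -> str:
    """Linear peptide SMILES with standard backbone amides and free termini.

    Length-1 input is rejected (a free amino acid is not a peptide), as is
    any letter outside the 20 standard one-letter codes.
    """
    seq = sequence.strip().upper()
    if len(seq) < 2:
        raise ReadError("peptide sequences must contain at least 2 residues")
    parts: list[str] = []
    for pos, letter in enumerate(seq, start=1):
        if letter == "G":
            parts.append("NCC(=O)")
        elif letter == "P":
            parts.append("N8[C@@H](CCC8)C(=O)")
        elif letter in _SIDE_CHAINS:
            parts.append(f"N[C@@H]({_SIDE_CHAINS[letter]})C(=O)")
        else:
            raise ReadError(
                f"unknown amino-acid code {letter!r} at position {pos}"
            )
    smiles = "".join(parts) + "O"
    if Chem.MolFromSmiles(smiles) is None:  # pragma: no cover - by construction
        raise ReadError(f"internal error: generated SMILES unparseable for {seq}")
    return smiles


# -- readers -------------------------------------------------------------------


def _iter_smiles_like(path: Path, fmt: str) -> Iterator[InputRecord]:
    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split(None, 1)
            text = fields[0]
            rid = fields[1].strip() if len(fields) > 1 else f"line-{lineno}"
            parse = Chem.MolFromSmiles if fmt == "smiles" else Chem.MolFromInchi
            if parse(text) is None:
                yield InputRecord(rid, text, fmt, error=f"unparseable {fmt} record")
            else:
                yield InputRecord(rid, text, fmt)


def _iter_sdf(path: Path) -> Iterator[InputRecord]:
    buffer: list[str] = []
    index = 0
    with path.open() as handle:
        for line in handle:
            if line.strip() == "$$$$":
                index += 1
                record = "".join(buffer)
                buffer = []
                title = record.splitlines()[0].strip() if record.splitlines() else ""
                rid = title or f"record-{index}"
                if Chem.MolFromMolBlock(record) is None:
                    yield InputRecord(rid, record, "sdf", error="unparseable molfile record")
                else:
                    yield InputRecord(rid, record, "sdf")
            else:
                buffer.append(line)
    if "".join(buffer).strip():
        index += 1
        record = "".join(buffer)
        title = record.splitlines()[0].strip()
        rid = title or f"record-{index}"
        if Chem.MolFromMolBlock(record) is None:
            yield InputRecord(rid, record, "sdf", error="unparseable molfile record")
        else:
            yield InputRecord(rid, record, "sdf")


def _iter_fasta(path: Path) -> Iterator[InputRecord]:
    from Bio import SeqIO

    for seq_record in SeqIO.parse(str(path), "fasta"):
        rid = seq_record.id or "unnamed"
        seq = str(seq_record.seq).upper()
        # A/C/G/T are also amino-acid codes, so short all-ACGT sequences are
        # ambiguous; call it a nucleotide only when the composition is
        # DNA/RNA-like and long enough, or contains U (not an amino acid).
        if seq and set(seq) <= _NUCLEOTIDE_LETTERS and (len(seq) >= 8 or "U" in seq):
            yield InputRecord(
                rid, seq, "fasta",
                error="nucleotide FASTA input is not supported (peptide sequences only)",
            )
            continue
        try:
            smiles = peptide_to_structure(seq)
        except ReadError as exc:
            yield InputRecord(rid, seq, "fasta", error=str(exc))
            continue
        yield InputRecord(rid, smiles, "smiles")


def read_structures(path: str | Path, fmt: str, strict: bool = False) -> Iterator[InputRecord]:
    """Stream input records from a structure file.

    Formats: ``smiles``/``inchi`` (one record per line, optional id column),
    ``sdf`` (MDL V2000, ``$$$$`` separated), ``fasta`` (protein; each
    sequence is converted to a peptide SMILES record).  Malformed records
    yield error entries; ``strict`` turns the first error into an exception.
    """
    path = Path(path)
    if not path.exists():
        raise ReadError(f"input file not found: {path}")
    if fmt in ("smiles", "inchi"):
        stream = _iter_smiles_like(path, fmt)
    elif fmt == "sdf":
        stream = _iter_sdf(path)
    elif fmt == "fasta":
        stream = _iter_fasta(path)
    else:
        raise ReadError(f"unknown input format {fmt!r}")
    for record in stream:
        if record.error and strict:
            raise ReadError(f"{record.record_id}: {record.error}")
        yield record


# -- result document model (doubles as the shipped JSON schema source) ---------


class CategoryRef(BaseModel):
    id: str
    name: str


class ExternalDescriptor(BaseModel):
    source: str
    foreign_id: str
    category_id: str


class ResultDocument(BaseModel):
    """One classification result as serialized to JSON."""

    record_id: str = ""
    input: str
    smiles: str
    kingdom: CategoryRef
    superclass: CategoryRef | None = None
    class_: CategoryRef | None = Field(default=None, alias="class")
    subclass: CategoryRef | None = None
    intermediate_nodes: list[CategoryRef] = []
    direct_parent: CategoryRef
    alternative_parents: list[CategoryRef] = []
    substituents: list[str] = []
    molecular_framework: str | None = None
    description: str = ""
    external_descriptors: list[ExternalDescriptor] = []
    shallow_classification: bool = False
    is_mixture: bool = False

    model_config = {"populate_by_name": True}


def _ref(result: ClassificationResult, cid: str | None) -> dict | None:
    if cid is None:
        return None
    return {"id": cid, "name": result.category_names.get(cid, "")}


def result_to_dict(result: ClassificationResult, record_id: str = "") -> dict:
    """Schema-conformant plain dict for one result (validated via the
    document model, so writers cannot drift from the shipped schema)."""
    doc = ResultDocument.model_validate(
        {
            "record_id": record_id,
            "input": result.input_string,
            "smiles": result.smiles,
            "kingdom": _ref(result, result.kingdom),
            "superclass": _ref(result, result.superclass),
            "class": _ref(result, result.class_),
            "subclass": _ref(result, result.subclass),
            "intermediate_nodes": [_ref(result, c) for c in result.intermediate_nodes],
            "direct_parent": _ref(result, result.direct_parent),
            "alternative_parents": [_ref(result, c) for c in result.alternative_parents],
            "substituents": result.substituents,
            "molecular_framework": result.molecular_framework,
            "description": result.description,
            "external_descriptors": [
                {"source": s, "foreign_id": f, "category_id": c}
                for s, f, c in result.external_descriptors
            ],
            "shallow_classification": result.shallow,
            "is_mixture": result.is_mixture,
        }
    )
    return doc.model_dump(by_alias=True)


CSV_HEADER = [
    "record_id", "smiles", "kingdom", "superclass", "class", "subclass",
    "direct_parent", "intermediate_nodes", "alternative_parents",
    "substituents", "molecular_framework", "description",
]


def write_results(
    results: Iterable[tuple[str, ClassificationResult]],
    fmt: str,
    path: str | Path,
) -> None:
    """Write ``(record_id, result)`` pairs as JSON, CSV (RFC 4180, UTF-8,
    fixed header), or SDF (structures with classification SD tags)."""
    path = Path(path)
    pairs = list(results)
    if fmt == "json":
        doc = {"results": [result_to_dict(r, rid) for rid, r in pairs]}
        path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    elif fmt == "csv":
        with path.open("w", newline="", encoding="utf-8") as handle:
            writer = csv.writer(handle)
            writer.writerow(CSV_HEADER)
            for rid, r in pairs:
                name = r.category_names.get
                writer.writerow([
                    rid,
                    r.smiles,
                    name(r.kingdom, ""),
                    name(r.superclass, "") if r.superclass else "",
                    name(r.class_, "") if r.class_ else "",
                    name(r.subclass, "") if r.subclass else "",
                    name(r.direct_parent, ""),
                    "|".join(name(c, "") for c in r.intermediate_nodes),
                    "|".join(name(c, "") for c in r.alternative_parents),
                    "|".join(r.substituents),
                    r.molecular_framework or "",
                    r.description,
                ])
    elif fmt == "sdf":
        writer = Chem.SDWriter(str(path))
        try:
            for rid, r in pairs:
                mol = Chem.MolFromSmiles(r.smiles)
                if mol is None:  # pragma: no cover - smiles come from RDKit
                    continue
                mol.SetProp("_Name", rid)
                name = r.category_names.get
                mol.SetProp("KINGDOM", name(r.kingdom, ""))
                mol.SetProp("DIRECT_PARENT", name(r.direct_parent, ""))
                if r.superclass:
                    mol.SetProp("SUPERCLASS", name(r.superclass, ""))
                if r.class_:
                    mol.SetProp("CLASS", name(r.class_, ""))
                if r.subclass:
                    mol.SetProp("SUBCLASS", name(r.subclass, ""))
                if r.alternative_parents:
                    mol.SetProp(
                        "ALTERNATIVE_PARENTS",
                        "|".join(name(c, "") for c in r.alternative_parents),
                    )
                if r.molecular_framework:
                    mol.SetProp("MOLECULAR_FRAMEWORK", r.molecular_framework)
                if r.description:
                    mol.SetProp("DESCRIPTION", r.description)
                writer.write(mol)
        finally:
            writer.close()
    else:
        raise ValueError(f"unknown output format {fmt!r}")
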
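"""Embedded result cache keyed by canonical structure hash.

Previously classified structures are looked up instead of recomputed.  The
key is the InChIKey of the standardized structure (so equivalent SMILES
spellings share one entry) and every entry is stamped with a fingerprint of
the taxonomy and rule-set texts: change either and all old entries miss.
The store is a single local SQLite file; a hit returns the exact bytes that
were stored.
"""

from __future__ import annotations

import hashlib
import sqlite3
from pathlib import Path

from rdkit import Chem

from .standardize import StandardizedMolecule

__all__ = ["CacheError", "ResultCache", "version_fingerprint"]


class CacheError(RuntimeError):
    pass


def version_fingerprint(taxonomy_text: str, ruleset_text: str) -> str:
    """Stable digest of the knowledge base backing cached results."""
    digest = hashlib.sha256()
    digest.update(taxonomy_text.encode())
    digest.update(b"\x00")
    digest.update(ruleset_text.encode())
    return digest.hexdigest()


def structure_key(mol: StandardizedMolecule) -> str:
    """Canonical hash of the standardized structure (InChIKey, falling back
    to canonical SMILES for species InChI cannot represent)."""
    key = Chem.MolToInchiKey(mol.mol)
    return key if key else "SMILES:" + mol.canonical_smiles


class ResultCache:
    """put/get of serialized results; fingerprint mismatch is a miss."""

    def __init__(self, path: str | Path):
        self.path = Path(path)
        try:
            self._db = sqlite3.connect(str(self.path))
            self._db.execute(
                "CREATE TABLE IF NOT EXISTS results ("
                "  key TEXT NOT NULL,"
                "  fingerprint TEXT NOT NULL,"
                "  payload TEXT NOT NULL,"
                "  PRIMARY KEY (key, fingerprint))"
            )
            self._db.commit()
        except sqlite3.DatabaseError as exc:
            raise CacheError(f"cannot open cache store {self.path}: {exc}") from None

    def get(self, mol: StandardizedMolecule, fingerprint: str) -> str | None:
        try:
            row = self._db.execute(
                "SELECT payload FROM results WHERE key = ? AND fingerprint = ?",
                (structure_key(mol), fingerprint),
            ).fetchone()
        except sqlite3.DatabaseError as exc:
            raise CacheError(f"corrupt cache store {self.path}: {exc}") from None
        return row[0] if row else None

    def put(self, mol: StandardizedMolecule, fingerprint: str, payload: str) -> None:
        try:
            self._db.execute(
                "INSERT OR REPLACE INTO results (key, fingerprint, payload) VALUES (?, ?, ?)",
                (structure_key(mol), fingerprint, payload),
            )
            self._db.commit()
        except sqlite3.DatabaseError as exc:
            raise CacheError(f"cannot write cache store {self.path}: {exc}") from None

    def close(self) -> None:
        self._db.close()

    def __enter__(self) -> "ResultCache":
        return self

    def __exit__(self, *exc) -> None:
        self.close()
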
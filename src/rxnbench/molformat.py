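"""Molecule-string services.

Canonicalization, randomized (non-canonical) SMILES enumeration, and the
"."-separated multi-molecule join/split convention used throughout the
pipeline. All chemistry goes through RDKit; a molecule is "valid" iff RDKit
can parse and sanitize it.

Multi-molecule inputs are kept as Python lists and only joined with "." at
serialization time, so a "." is always a molecule separator and never part
of a component string.
"""

from __future__ import annotations

import random
from functools import lru_cache
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger

from .errors import InvalidMoleculeError

# RDKit logs every failed parse at error level; invalid candidates are an
# expected, scored event here, so silence the C++ logger once at import.
RDLogger.DisableLog("rdApp.*")


def mol_from_smiles(smiles: str) -> Chem.Mol:
    """Parse a SMILES string, raising :class:`InvalidMoleculeError` on failure."""
    if not isinstance(smiles, str) or not smiles:
        raise InvalidMoleculeError(f"not a molecule string: {smiles!r}")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidMoleculeError(f"unparseable SMILES: {smiles!r}")
    return mol


@lru_cache(maxsize=262_144)
def canonicalize(smiles: str) -> str:
    """Return the RDKit-canonical SMILES of ``smiles``.

    Idempotent: ``canonicalize(canonicalize(s)) == canonicalize(s)``.
    Results are memoized (canonicalization dominates metric computation).
    """
    return Chem.MolToSmiles(mol_from_smiles(smiles))


def is_valid_smiles(smiles: str) -> bool:
    """True iff the string parses and sanitizes as a molecule."""
    return bool(smiles) and Chem.MolFromSmiles(smiles) is not None


def canonical_equal(a: str, b: str) -> bool:
    """Do two SMILES strings denote the same molecule?"""
    return canonicalize(a) == canonicalize(b)


def randomize_smiles(smiles: str, rng: random.Random) -> str:
    """Re-serialize a molecule as a random non-canonical SMILES string.

    The atom order is uniformly permuted before writing, which randomizes
    both the root (first) atom of the string and the direction in which
    branches and rings are enumerated. The output always encodes the same
    molecule: ``canonicalize(randomize_smiles(s, rng)) == canonicalize(s)``.
    """
    mol = mol_from_smiles(smiles)
    n = mol.GetNumAtoms()
    if n <= 1:
        return Chem.MolToSmiles(mol, canonical=False)
    perm = list(range(n))
    rng.shuffle(perm)
    shuffled = Chem.RenumberAtoms(mol, perm)
    return Chem.MolToSmiles(shuffled, canonical=False)


def join_molecules(molecules: Iterable[str]) -> str:
    """Join component molecule strings with the "." separator token."""
    return ".".join(molecules)


def split_molecules(text: str) -> list[str]:
    """Split a "."-joined multi-molecule string back into components.

    The empty string maps to the empty list (inverse of ``join_molecules([])``).
    """
    if text == "":
        return []
    return text.split(".")


def canonical_molecule_set(text: str) -> frozenset[str]:
    """Canonical forms of all parseable components of a "."-joined string.

    Raises :class:`InvalidMoleculeError` if any component fails to parse;
    callers that tolerate invalid components (lenient scoring) should use
    :func:`partition_valid` instead.
    """
    return frozenset(canonicalize(m) for m in split_molecules(text))


def partition_valid(molecules: Sequence[str]) -> tuple[list[str], list[str]]:
    """Split molecule strings into (canonicalized valid, raw invalid)."""
    valid: list[str] = []
    invalid: list[str] = []
    for m in molecules:
        if is_valid_smiles(m):
            valid.append(canonicalize(m))
        else:
            invalid.append(m)
    return valid, invalid
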
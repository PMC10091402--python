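"""Self-contained SELFIES codec for the neutral organic subset.

SELFIES is a molecular string notation in which every syntactically valid
token string decodes to a valid molecule: bond orders, branch lengths and
ring offsets are *derived* under valence constraints rather than trusted,
so malformed combinations are clamped or skipped instead of failing.

This codec implements that derivation semantics for neutral, non-isotopic,
non-stereo molecules over the element set {C, N, O, S, P, F, Cl, Br, I}
(aromatic rings are kekulized before encoding). Molecules outside the
subset — charged species, isotopes, stereocenters, hypervalent S/P — are
*not encodable* and are represented by the single fallback token "?",
which is carried through datasets verbatim and is not decodable.

Token inventory (a compatible subset of the standard SELFIES alphabet):

* atom tokens ``[C] [=C] [#C] [N] [=N] [#N] [O] [=O] [S] [=S] [P] [F]
  [Cl] [Br] [I]`` — the optional ``=``/``#`` prefix requests the bond
  order to the previous atom;
* ``[Branch1] [=Branch1] [#Branch1]`` and the ``Branch2`` forms — open a
  side chain whose token length is given by the following index token(s);
* ``[Ring1] [=Ring1] [Ring2] [=Ring2]`` — close a ring to the atom whose
  derivation-order offset is given by the following index token(s);
* every token doubles as an index symbol via ``INDEX_ALPHABET`` (base-16
  digits), as in the reference SELFIES grammar.
"""

from __future__ import annotations

import re

from rdkit import Chem

from .errors import InvalidMoleculeError, NotDecodableError, TokenizationError
from .molformat import mol_from_smiles

FALLBACK_TOKEN = "?"

#: Maximum bonding capacity assumed per element (implicit H fills the rest).
VALENCES = {"C": 4, "N": 3, "O": 2, "S": 2, "P": 3, "F": 1, "Cl": 1, "Br": 1, "I": 1}

BOND_PREFIX = {"": 1, "=": 2, "#": 3}
PREFIX_OF_ORDER = {1: "", 2: "=", 3: "#"}

#: Base-16 digit alphabet used to read integers out of ordinary tokens,
#: mirroring the reference grammar so index tokens look like atom tokens.
INDEX_ALPHABET = [
    "[C]", "[Ring1]", "[Ring2]", "[Branch1]", "[=Branch1]", "[#Branch1]",
    "[Branch2]", "[=Branch2]", "[#Branch2]", "[O]", "[N]", "[=N]", "[=C]",
    "[#C]", "[S]", "[P]",
]
_INDEX_OF = {tok: i for i, tok in enumerate(INDEX_ALPHABET)}

_TOKEN_RE = re.compile(r"\[[^\[\]]*\]")
_ATOM_TOKEN_RE = re.compile(r"\[([=#]?)(C|N|O|S|P|F|Cl|Br|I)\]")
_BRANCH_TOKEN_RE = re.compile(r"\[([=#]?)Branch([12])\]")
_RING_TOKEN_RE = re.compile(r"\[([=#]?)Ring([12])\]")


def split_selfies(selfies: str) -> list[str]:
    """Split a SELFIES string into bracket tokens.

    Raises :class:`TokenizationError` if any character falls outside a
    ``[...]`` group (the "?" fallback is handled by callers, not here).
    """
    tokens = _TOKEN_RE.findall(selfies)
    if "".join(tokens) != selfies:
        raise TokenizationError(f"not a bracket-token string: {selfies!r}")
    return tokens


def _token_index(token: str) -> int:
    return _INDEX_OF.get(token, 0)


def _read_index(tokens: list[str], pos: int, n_digits: int) -> tuple[int, int]:
    """Read an ``n_digits``-token base-16 integer starting at ``pos``."""
    value = 0
    for _ in range(n_digits):
        digit = _token_index(tokens[pos]) if pos < len(tokens) else 0
        value = value * 16 + digit
        pos += 1
    return value, pos


def _encode_index(value: int) -> list[str]:
    """Index tokens for ``value`` (1 token if < 16, else 2; capped at 255)."""
    if value < 16:
        return [INDEX_ALPHABET[value]]
    return [INDEX_ALPHABET[value // 16], INDEX_ALPHABET[value % 16]]


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------


class _Builder:
    """Accumulates atoms and bonds during derivation."""

    def __init__(self) -> None:
        self.mol = Chem.RWMol()
        self.capacity: list[int] = []  # remaining valence per atom index

    def add_atom(self, symbol: str, attach_to: int | None, order: int) -> int:
        idx = self.mol.AddAtom(Chem.Atom(symbol))
        self.capacity.append(VALENCES[symbol])
        if attach_to is not None:
            order = min(order, self.capacity[attach_to], self.capacity[idx])
            order = max(order, 1)
            self.mol.AddBond(attach_to, idx, Chem.BondType.values[order])
            self.capacity[attach_to] -= order
            self.capacity[idx] -= order
        return idx

    def add_ring_bond(self, a: int, b: int, order: int) -> None:
        if a == b or self.mol.GetBondBetweenAtoms(a, b) is not None:
            return
        order = min(order, self.capacity[a], self.capacity[b])
        if order < 1:
            return
        self.mol.AddBond(a, b, Chem.BondType.values[order])
        self.capacity[a] -= order
        self.capacity[b] -= order


def _derive(tokens: list[str], builder: _Builder, prev: int | None,
            first_bond_order: int | None) -> None:
    """Consume ``tokens``, growing the molecule from atom ``prev``.

    ``first_bond_order`` overrides the bond-order prefix of the first atom
    token (used for branch attachment). Derivation of this chain stops
    early when the attachment atom runs out of valence capacity, which is
    what makes arbitrary token strings decodable.
    """
    pos = 0
    first = True
    while pos < len(tokens):
        token = tokens[pos]
        m = _ATOM_TOKEN_RE.fullmatch(token)
        if m:
            if prev is not None and builder.capacity[prev] == 0:
                return
            order = BOND_PREFIX[m.group(1)]
            if first and first_bond_order is not None:
                order = first_bond_order
            prev = builder.add_atom(m.group(2), prev, order)
            first = False
            pos += 1
            continue
        m = _BRANCH_TOKEN_RE.fullmatch(token)
        if m:
            n_digits = int(m.group(2))
            value, pos = _read_index(tokens, pos + 1, n_digits)
            length = value + 1
            branch_tokens = tokens[pos:pos + length]
            pos += length
            # a branch needs an anchor atom with spare valence
            if prev is not None and builder.capacity[prev] >= 1:
                _derive(branch_tokens, builder, prev, BOND_PREFIX[m.group(1)])
            continue
        m = _RING_TOKEN_RE.fullmatch(token)
        if m:
            n_digits = int(m.group(2))
            value, pos = _read_index(tokens, pos + 1, n_digits)
            if prev is not None:
                target = prev - (value + 1)
                if target >= 0:
                    builder.add_ring_bond(prev, target, BOND_PREFIX[m.group(1)])
            continue
        # unknown but well-formed bracket token: no-op
        pos += 1


def decode(selfies: str) -> str:
    """Decode a SELFIES token string to a SMILES string.

    Raises :class:`NotDecodableError` for the "?" fallback token, for the
    empty string, and for strings that are not bracket-token sequences.
    Every well-formed non-empty token string yields a valid molecule.
    """
    if selfies == FALLBACK_TOKEN:
        raise NotDecodableError("the '?' fallback token carries no structure")
    if not selfies:
        raise NotDecodableError("empty SELFIES string")
    try:
        tokens = split_selfies(selfies)
    except TokenizationError as exc:
        raise NotDecodableError(str(exc)) from exc
    builder = _Builder()
    _derive(tokens, builder, None, None)
    if builder.mol.GetNumAtoms() == 0:
        raise NotDecodableError(f"no atoms derivable from {selfies!r}")
    mol = builder.mol.GetMol()
    Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(mol)


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------


def _encodable_atom(atom: Chem.Atom) -> bool:
    sym = atom.GetSymbol()
    if sym not in VALENCES:
        return False
    if atom.GetFormalCharge() != 0 or atom.GetIsotope() != 0:
        return False
    if atom.GetNumRadicalElectrons() != 0:
        return False
    if atom.GetChiralTag() != Chem.ChiralType.CHI_UNSPECIFIED:
        return False
    # explicit valence must fit the subset table (no hypervalent S/P)
    return atom.GetExplicitValence() <= VALENCES[sym]


def _encode_mol(mol: Chem.Mol) -> list[str]:
    """Emit tokens by depth-first traversal with ring back-edges."""
    n = mol.GetNumAtoms()
    position = {}  # atom idx -> derivation-order position
    ring_bonds_done: set[tuple[int, int]] = set()

    def bond_order(a: int, b: int) -> int:
        bt = mol.GetBondBetweenAtoms(a, b).GetBondType()
        return {Chem.BondType.SINGLE: 1, Chem.BondType.DOUBLE: 2,
                Chem.BondType.TRIPLE: 3}[bt]

    def walk(atom_idx: int, parent: int | None) -> list[str]:
        tokens: list[str] = []
        position[atom_idx] = len(position)
        prefix = ""
        if parent is not None:
            prefix = PREFIX_OF_ORDER[bond_order(parent, atom_idx)]
        tokens.append(f"[{prefix}{mol.GetAtomWithIdx(atom_idx).GetSymbol()}]")

        # close rings back to already-placed atoms
        for nbr in mol.GetAtomWithIdx(atom_idx).GetNeighbors():
            j = nbr.GetIdx()
            if j == parent or j not in position:
                continue
            key = (min(atom_idx, j), max(atom_idx, j))
            if key in ring_bonds_done:
                continue
            ring_bonds_done.add(key)
            offset = position[atom_idx] - position[j] - 1
            order = bond_order(atom_idx, j)
            size = 1 if offset < 16 else 2
            if offset > 255 or order > 2:
                raise InvalidMoleculeError("ring closure outside codec subset")
            tokens.append(f"[{PREFIX_OF_ORDER[order]}Ring{size}]")
            tokens.extend(_encode_index(offset) if size == 2 else
                          [INDEX_ALPHABET[offset]])

        children = [nbr.GetIdx() for nbr in mol.GetAtomWithIdx(atom_idx).GetNeighbors()
                    if nbr.GetIdx() != parent]
        for child in children:
            # ring closures in an earlier subtree may have placed this child
            if child in position:
                continue
            sub = walk(child, atom_idx)
            # the branch-vs-chain decision is made after the walk: only then
            # do we know whether any sibling still needs the main chain
            remaining = [c for c in children if c not in position]
            if remaining:
                order = bond_order(atom_idx, child)
                length = len(sub)
                size = 1 if length <= 16 else 2
                if length > 256:
                    raise InvalidMoleculeError("branch too long for codec subset")
                tokens.append(f"[{PREFIX_OF_ORDER[order]}Branch{size}]")
                tokens.extend(_encode_index(length - 1))
                # the Branch token carries the bond order; the branch's first
                # atom token is emitted plain
                sub[0] = re.sub(r"^\[[=#]?", "[", sub[0], count=1)
            tokens.extend(sub)
        return tokens

    tokens = walk(0, None)
    if len(position) != n:
        raise InvalidMoleculeError("disconnected molecule component")
    return tokens


def encode(smiles: str) -> str:
    """Encode a SMILES string as SELFIES, or return "?" if not encodable.

    Total function: parse failures, charged/isotopic/stereo/hypervalent
    molecules, and anything else outside the codec subset all map to the
    fallback token, which downstream stages carry verbatim.
    """
    try:
        mol = mol_from_smiles(smiles)
        Chem.Kekulize(mol, clearAromaticFlags=True)
        if mol.GetNumAtoms() == 0:
            return FALLBACK_TOKEN
        if len(Chem.GetMolFrags(mol)) != 1:
            return FALLBACK_TOKEN
        if not all(_encodable_atom(a) for a in mol.GetAtoms()):
            return FALLBACK_TOKEN
        for bond in mol.GetBonds():
            if bond.GetBondType() not in (Chem.BondType.SINGLE,
                                          Chem.BondType.DOUBLE,
                                          Chem.BondType.TRIPLE):
                return FALLBACK_TOKEN
            if bond.GetStereo() != Chem.BondStereo.STEREONONE:
                return FALLBACK_TOKEN
        tokens = _encode_mol(mol)
    except (InvalidMoleculeError, Chem.KekulizeException, ValueError):
        return FALLBACK_TOKEN
    return "".join(tokens)
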
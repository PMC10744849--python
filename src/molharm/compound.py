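"""Compound data model and molfile/KCF input-output.

A :class:`Compound` is an undirected labeled graph over *non-hydrogen* atoms:
hydrogens are removed at parse time and every downstream algorithm (coloring,
distances, substructure search) sees heavy atoms only.  Bonds carry the
standard ctfile integer order: 1 single, 2 double, 3 triple, 4 aromatic.

R-group placeholder atoms (generic "any substituent" markers) are recognized
from a configurable marker set; a compound containing one is a *generic*
compound describing a family of structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

#: Atom symbols treated as R-group placeholders; KCF atom types beginning
#: with "R" are additionally treated as R regardless of the symbol.
DEFAULT_R_MARKERS = frozenset({"R", "R#", "*", "X"})

VALID_BOND_ORDERS = (1, 2, 3, 4)


class ParseError(ValueError):
    """A structure file could not be parsed; the message names the line."""


class UnsupportedDialectError(ParseError):
    """The file uses a dialect outside the supported subset (e.g. V3000)."""


class CapacityError(ValueError):
    """The structure exceeds a fixed-width format limit."""


@dataclass
class Atom:
    """One heavy atom: element label, charge, ring membership, optional KCF type."""

    index: int
    element: str
    is_R: bool = False
    charge: int = 0
    in_ring: bool = False
    kcf_type: Optional[str] = None
    coords: Optional[tuple[float, float, float]] = None


@dataclass
class Bond:
    """Undirected bond between two atom indices with integer order 1..4."""

    first_atom: int
    second_atom: int
    order: int

    def key(self) -> frozenset[int]:
        return frozenset((self.first_atom, self.second_atom))


@dataclass
class Compound:
    """Labeled molecular graph of heavy atoms; may hold several components (salts)."""

    id: str
    atoms: list[Atom] = field(default_factory=list)
    bonds: list[Bond] = field(default_factory=list)
    source: str = "synthetic"

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        n = len(self.atoms)
        seen: set[frozenset[int]] = set()
        for b in self.bonds:
            if b.first_atom == b.second_atom:
                raise ValueError(f"self-bond on atom {b.first_atom} in {self.id}")
            if not (0 <= b.first_atom < n and 0 <= b.second_atom < n):
                raise ValueError(f"bond endpoint out of range in {self.id}")
            if b.order not in VALID_BOND_ORDERS:
                raise ValueError(f"bond order {b.order} not in {VALID_BOND_ORDERS}")
            k = b.key()
            if k in seen:
                raise ValueError(f"duplicate bond {sorted(k)} in {self.id}")
            seen.add(k)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def neighbors(self, i: int) -> list[tuple[int, int]]:
        """(neighbor index, bond order) pairs of atom ``i``."""
        out = []
        for b in self.bonds:
            if b.first_atom == i:
                out.append((b.second_atom, b.order))
            elif b.second_atom == i:
                out.append((b.first_atom, b.order))
        return out

    def bond_order(self, i: int, j: int) -> int:
        """Order of the i–j bond, or 0 if not bonded."""
        for b in self.bonds:
            if {b.first_atom, b.second_atom} == {i, j}:
                return b.order
        return 0

    def r_atom_indices(self) -> list[int]:
        return [a.index for a in self.atoms if a.is_R]

    def copy(self, new_id: Optional[str] = None) -> "Compound":
        return Compound(
            id=new_id if new_id is not None else self.id,
            atoms=[Atom(a.index, a.element, a.is_R, a.charge, a.in_ring, a.kcf_type, a.coords)
                   for a in self.atoms],
            bonds=[Bond(b.first_atom, b.second_atom, b.order) for b in self.bonds],
            source=self.source,
        )


def structurally_equal(a: Compound, b: Compound) -> bool:
    """Same atom list (element, charge, R flag, order) and same bond set; coords ignored."""
    if a.n_atoms != b.n_atoms or len(a.bonds) != len(b.bonds):
        return False
    for x, y in zip(a.atoms, b.atoms):
        if (x.element, x.charge, x.is_R) != (y.element, y.charge, y.is_R):
            return False
    bonds_a = {(b_.key(), b_.order) for b_ in a.bonds}
    bonds_b = {(b_.key(), b_.order) for b_ in b.bonds}
    return bonds_a == bonds_b


def _is_r_symbol(symbol: str, r_markers: Iterable[str]) -> bool:
    return symbol in set(r_markers)


# ---------------------------------------------------------------------------
# molfile V2000
# ---------------------------------------------------------------------------

def parse_molfile(text: str, compound_id: str = "",
                  r_markers: Iterable[str] = DEFAULT_R_MARKERS) -> Compound:
    """Parse an MDL molfile (V2000) into a :class:`Compound`.

    Hydrogens and their bonds are removed; remaining atoms keep file order.
    Charges are taken from ``M  CHG`` property lines when present (they
    supersede the atom-block charge column, which is ignored).  V3000 files
    are rejected.
    """
    lines = text.splitlines()
    if len(lines) < 4:
        raise ParseError("molfile truncated before counts line (line 4)")
    counts = lines[3]
    if "V3000" in counts:
        raise UnsupportedDialectError("V3000 molfiles are not supported (counts line, line 4)")
    try:
        n_atoms = int(counts[0:3])
        n_bonds = int(counts[3:6])
    except (ValueError, IndexError) as exc:
        raise ParseError(f"malformed counts line (line 4): {counts!r}") from exc

    atom_start = 4
    bond_start = atom_start + n_atoms
    if len(lines) < bond_start + n_bonds:
        raise ParseError(f"truncated: expected {n_atoms} atom + {n_bonds} bond lines "
                         f"after line {atom_start}")

    raw_atoms: list[tuple[str, tuple[float, float, float]]] = []
    for k in range(n_atoms):
        line = lines[atom_start + k]
        lineno = atom_start + k + 1
        try:
            x, y, z = float(line[0:10]), float(line[10:20]), float(line[20:30])
            element = line[31:34].strip()
        except (ValueError, IndexError):
            parts = line.split()
            if len(parts) < 4:
                raise ParseError(f"malformed atom line {lineno}: {line!r}")
            x, y, z = float(parts[0]), float(parts[1]), float(parts[2])
            element = parts[3]
        if not element:
            raise ParseError(f"empty element symbol on atom line {lineno}")
        raw_atoms.append((element, (x, y, z)))

    raw_bonds: list[tuple[int, int, int]] = []
    for k in range(n_bonds):
        line = lines[bond_start + k]
        lineno = bond_start + k + 1
        try:
            i, j, order = int(line[0:3]), int(line[3:6]), int(line[6:9])
        except (ValueError, IndexError):
            parts = line.split()
            if len(parts) < 3:
                raise ParseError(f"malformed bond line {lineno}: {line!r}")
            i, j, order = int(parts[0]), int(parts[1]), int(parts[2])
        if not (1 <= i <= n_atoms and 1 <= j <= n_atoms):
            raise ParseError(f"bond endpoint out of range on line {lineno}")
        raw_bonds.append((i - 1, j - 1, order))

    charges = {}
    for line in lines[bond_start + n_bonds:]:
        if line.startswith("M  CHG"):
            parts = line.split()
            count = int(parts[2])
            for c in range(count):
                charges[int(parts[3 + 2 * c]) - 1] = int(parts[4 + 2 * c])
        elif line.startswith("M  END"):
            break

    keep = [k for k, (el, _) in enumerate(raw_atoms) if el != "H"]
    remap = {old: new for new, old in enumerate(keep)}
    atoms = []
    for old in keep:
        el, xyz = raw_atoms[old]
        atoms.append(Atom(index=remap[old], element=el,
                          is_R=_is_r_symbol(el, r_markers),
                          charge=charges.get(old, 0), coords=xyz))
    bonds = [Bond(remap[i], remap[j], order) for i, j, order in raw_bonds
             if i in remap and j in remap]
    return Compound(id=compound_id, atoms=atoms, bonds=bonds, source="molfile")


def write_molfile(c: Compound) -> str:
    """Serialize to a V2000 molfile; round-trips through :func:`parse_molfile`."""
    if c.n_atoms > 999:
        raise CapacityError(f"{c.n_atoms} atoms exceed the V2000 fixed-width limit of 999")
    out = [c.id, "  molharm", ""]
    out.append(f"{c.n_atoms:3d}{len(c.bonds):3d}  0  0  0  0  0  0  0  0999 V2000")
    for a in c.atoms:
        x, y, z = a.coords if a.coords is not None else (0.0, 0.0, 0.0)
        out.append(f"{x:10.4f}{y:10.4f}{z:10.4f} {a.element:<3s} 0  0  0  0  0  0  0  0  0  0  0  0")
    for b in c.bonds:
        out.append(f"{b.first_atom + 1:3d}{b.second_atom + 1:3d}{b.order:3d}  0")
    charged = [(a.index + 1, a.charge) for a in c.atoms if a.charge != 0]
    for start in range(0, len(charged), 8):  # ctfile allows 8 entries per M CHG line
        chunk = charged[start:start + 8]
        out.append("M  CHG" + f"{len(chunk):3d}" +
                   "".join(f"{i:4d}{v:4d}" for i, v in chunk))
    out.append("M  END")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# KCF
# ---------------------------------------------------------------------------

def parse_kcf(text: str, compound_id: str = "",
              r_markers: Iterable[str] = DEFAULT_R_MARKERS) -> Compound:
    """Parse a KEGG KCF record (ENTRY/ATOM/BOND blocks, 1-based indices).

    Per-atom KEGG type codes (e.g. ``C8y``) are stored in ``kcf_type``; a
    type beginning with "R" marks an R-group atom.
    """
    lines = text.splitlines()
    entry_id = compound_id
    atom_lines: list[str] = []
    bond_lines: list[str] = []
    section = None
    n_atoms_declared = n_bonds_declared = None
    for line in lines:
        stripped = line.strip()
        if not stripped or stripped == "///":
            continue
        head = line[:12].strip()
        if head:
            section = head
            rest = line[12:].split()
            if section == "ENTRY" and rest and not entry_id:
                entry_id = rest[0]
            elif section == "ATOM" and rest:
                n_atoms_declared = int(rest[0])
            elif section == "BOND" and rest:
                n_bonds_declared = int(rest[0])
            continue
        if section == "ATOM":
            atom_lines.append(stripped)
        elif section == "BOND":
            bond_lines.append(stripped)

    if n_atoms_declared is None:
        raise ParseError("KCF record has no ATOM block")
    if n_bonds_declared is None:
        raise ParseError("KCF record has no BOND block")
    if len(atom_lines) != n_atoms_declared:
        raise ParseError(f"ATOM block declares {n_atoms_declared} atoms, "
                         f"found {len(atom_lines)} lines")
    if len(bond_lines) != n_bonds_declared:
        raise ParseError(f"BOND block declares {n_bonds_declared} bonds, "
                         f"found {len(bond_lines)} lines")

    raw = []
    for line in atom_lines:
        parts = line.split()
        if len(parts) < 3:
            raise ParseError(f"malformed KCF atom line: {line!r}")
        kcf_type, element = parts[1], parts[2]
        xyz = tuple(float(v) for v in parts[3:6]) if len(parts) >= 5 else None
        if xyz is not None and len(xyz) == 2:
            xyz = (xyz[0], xyz[1], 0.0)
        raw.append((element, kcf_type, xyz))

    keep = [k for k, (el, _, _) in enumerate(raw) if el != "H"]
    remap = {old: new for new, old in enumerate(keep)}
    atoms = []
    for old in keep:
        el, kcf_type, xyz = raw[old]
        is_r = kcf_type.startswith("R") or _is_r_symbol(el, r_markers)
        atoms.append(Atom(index=remap[old], element=el, is_R=is_r,
                          kcf_type=kcf_type, coords=xyz))

    bonds = []
    for line in bond_lines:
        parts = line.split()
        if len(parts) < 4:
            raise ParseError(f"malformed KCF bond line: {line!r}")
        i, j, order = int(parts[1]) - 1, int(parts[2]) - 1, int(parts[3])
        if i in remap and j in remap:
            bonds.append(Bond(remap[i], remap[j], order))
    return Compound(id=entry_id or compound_id, atoms=atoms, bonds=bonds, source="kcf")


# ---------------------------------------------------------------------------
# derived structure
# ---------------------------------------------------------------------------

def adjacency_matrix(c: Compound) -> np.ndarray:
    """n×n symmetric integer matrix; entry = bond order, 0 when not bonded."""
    n = c.n_atoms
    N = np.zeros((n, n), dtype=np.int64)
    for b in c.bonds:
        N[b.first_atom, b.second_atom] = b.order
        N[b.second_atom, b.first_atom] = b.order
    return N


def detect_rings(c: Compound) -> list[bool]:
    """Flag each atom as in a ring iff it touches a non-bridge (cycle) edge.

    Bridges are found with one depth-first pass (low-link values); every
    non-bridge edge lies on some cycle.  Also caches the set of ring-bond
    atom pairs on the compound (``c.ring_bonds``) and updates each atom's
    ``in_ring`` flag.
    """
    n = c.n_atoms
    adj: list[list[tuple[int, int]]] = [[] for _ in range(n)]
    for e, b in enumerate(c.bonds):
        adj[b.first_atom].append((b.second_atom, e))
        adj[b.second_atom].append((b.first_atom, e))

    disc = [-1] * n
    low = [0] * n
    is_bridge = [False] * len(c.bonds)
    timer = 0
    for root in range(n):
        if disc[root] != -1:
            continue
        stack: list[tuple[int, int, int]] = [(root, -1, 0)]  # node, parent edge, next child slot
        while stack:
            v, pe, ci = stack[-1]
            if ci == 0:
                disc[v] = low[v] = timer
                timer += 1
            if ci < len(adj[v]):
                stack[-1] = (v, pe, ci + 1)
                w, e = adj[v][ci]
                if e == pe:
                    continue
                if disc[w] == -1:
                    stack.append((w, e, 0))
                else:
                    low[v] = min(low[v], disc[w])
            else:
                stack.pop()
                if stack:
                    u = stack[-1][0]
                    low[u] = min(low[u], low[v])
                    if low[v] > disc[u]:
                        is_bridge[pe] = True

    ring_bonds = {c.bonds[e].key() for e in range(len(c.bonds)) if not is_bridge[e]}
    flags = [False] * n
    for k in ring_bonds:
        for i in k:
            flags[i] = True
    for a in c.atoms:
        a.in_ring = flags[a.index]
    c.ring_bonds = ring_bonds  # type: ignore[attr-defined]
    return flags


def ring_bond_set(c: Compound) -> set[frozenset[int]]:
    """Atom-pair keys of all cycle (non-bridge) bonds; runs ring perception if needed."""
    if not hasattr(c, "ring_bonds"):
        detect_rings(c)
    return c.ring_bonds  # type: ignore[attr-defined]


_HILL_FIRST = ("C", "H")


def molecular_formula(c: Compound) -> str:
    """Heavy-atom formula in Hill order, with R-group count appended as ``R<k>``.

    Hydrogens are never present in a parsed compound, so this is a
    heavy-atom-only formula (no implicit-H valence model); counts of 1 omit
    the digit except for R, which always carries its count.
    """
    counts: dict[str, int] = {}
    n_r = 0
    for a in c.atoms:
        if a.is_R:
            n_r += 1
        else:
            counts[a.element] = counts.get(a.element, 0) + 1
    ordered = [e for e in _HILL_FIRST if e in counts]
    ordered += sorted(e for e in counts if e not in _HILL_FIRST)
    parts = [f"{e}{counts[e]}" if counts[e] > 1 else e for e in ordered]
    if n_r:
        parts.append(f"R{n_r}")
    return "".join(parts)


def element_counts(c: Compound, include_r: bool = False) -> dict[str, int]:
    """Multiset of element symbols (R atoms pooled under "R" when included)."""
    counts: dict[str, int] = {}
    for a in c.atoms:
        if a.is_R:
            if include_r:
                counts["R"] = counts.get("R", 0) + 1
        else:
            counts[a.element] = counts.get(a.element, 0) + 1
    return counts
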
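"""Neighborhood-specific layered graph coloring and canonical identifiers.

Each atom receives a color string per layer.  Layer 0 is the element symbol
alone (R atoms collapse to ``"R"``); the layer-k color combines the atom's
layer-(k-1) color with the lexicographically sorted multiset of
``(bond order, neighbor layer-(k-1) color)`` pairs.  This is 1-dimensional
Weisfeiler–Lehman refinement over the bond-labeled molecular graph, so a
layer-k color is a deterministic summary of the radius-k neighborhood of
the atom.  Colors are full strings rather than hashes: equality is exact and
reproducible across runs, platforms, and between different compounds (the
latter is what the generic-compound matching criterion relies on).

The sorted final-layer colors, prefixed by the heavy-atom formula, form the
canonical compound identifier used for exact cross-database matching.
"""

from __future__ import annotations

from dataclasses import dataclass

from molharm.compound import Compound, molecular_formula


@dataclass
class AtomColorTable:
    """Per-atom color strings for layers ``0..L`` of one compound."""

    compound_id: str
    colors: list[list[str]]  # colors[atom][layer]
    L: int

    def to_json_dict(self) -> dict:
        return {"compound_id": self.compound_id, "L": self.L, "colors": self.colors}


def _base_color(atom, include_charge: bool) -> str:
    if atom.is_R:
        return "R"
    if include_charge and atom.charge:
        return f"{atom.element}{atom.charge:+d}"
    return atom.element


def atom_colors(c: Compound, max_layer: int | str = "auto",
                include_charge: bool = False) -> AtomColorTable:
    """Compute the layered color table of a compound.

    With ``max_layer="auto"`` refinement runs until the induced partition of
    atoms stabilizes, then one extra confirming layer is kept; the number of
    layers never exceeds the atom count.  Colors are invariant under any
    relabeling of atom indices, and the partition at layer k+1 always refines
    the one at layer k.
    """
    n = c.n_atoms
    if n == 0:
        return AtomColorTable(c.id, [], 0)
    neighbors = [c.neighbors(i) for i in range(n)]
    layers: list[list[str]] = [[_base_color(a, include_charge) for a in c.atoms]]

    auto = max_layer == "auto"
    limit = (n + 1) if auto else int(max_layer) + 1  # total layer count incl. layer 0
    while len(layers) < limit:
        prev = layers[-1]
        nxt = []
        for i in range(n):
            entries = sorted(f"({o},{prev[j]})" for j, o in neighbors[i])
            nxt.append(f"[{prev[i]}|{''.join(entries)}]")
        layers.append(nxt)
        # partition stable once the new colors induce the same grouping; the
        # stable layer itself is kept as the confirming layer
        if auto and _partition(layers[-1]) == _partition(layers[-2]):
            break
    colors = [[layers[k][i] for k in range(len(layers))] for i in range(n)]
    return AtomColorTable(c.id, colors, len(layers) - 1)


def _partition(colors: list[str]) -> list[tuple[int, ...]]:
    groups: dict[str, list[int]] = {}
    for i, col in enumerate(colors):
        groups.setdefault(col, []).append(i)
    return sorted(tuple(v) for v in groups.values())


def color_at_level(table: AtomColorTable, atom: int, level: int) -> str:
    """Color of one atom at a requested layer; beyond L the stable colors apply."""
    if level < 0:
        raise ValueError(f"color level must be non-negative, got {level}")
    return table.colors[atom][min(level, table.L)]


def compound_identifier(c: Compound, include_charge: bool = False) -> str:
    """Canonical identifier: heavy-atom formula + sorted final-layer atom colors.

    Invariant under atom reordering; equal for isomorphic labeled graphs.
    Like any 1-WL scheme it cannot separate certain highly regular
    non-isomorphic graphs, which is why exact matching additionally compares
    the bond-order multiset as a safety net.
    """
    table = atom_colors(c, include_charge=include_charge)
    final = sorted(col[-1] for col in table.colors)
    return molecular_formula(c) + "|" + "&".join(final)
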
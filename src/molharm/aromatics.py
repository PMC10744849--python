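"""Aromatic substructure library: construction, detection, bond curation.

KEGG KCF records carry per-atom type codes that mark aromatic atoms (e.g.
``C8y`` for an aromatic carbon).  The :class:`AromaticManager` harvests the
connected components of aromatic-typed atoms from a KCF corpus into a
deduplicated fragment library, locates those fragments in arbitrary
compounds with the ring-aware, kekulization-tolerant substructure search,
and rewrites matched ring bonds to the aromatic order 4 so that different
kekulizations of the same ring system collapse to one canonical structure
(and hence one compound identifier).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

from molharm.compound import Atom, Bond, Compound, detect_rings
from molharm.coloring import compound_identifier
from molharm.substructure import MatchOptions, find_mappings

logger = logging.getLogger(__name__)

#: KEGG atom-type families treated as aromatic by default: aromatic carbons
#: (C8x/C8y) and aromatic nitrogens (N4x/N4y ring NH/N, N5x/N5y pyridine-like).
DEFAULT_AROMATIC_TYPES = frozenset({"C8x", "C8y", "N4x", "N4y", "N5x", "N5y"})

DEFAULT_NODE_BUDGET = 10 ** 6


@dataclass
class AromaticSubstructure:
    """One extracted ring-system fragment with its canonical identifier."""

    fragment: Compound
    identifier: str
    provenance: list[str] = field(default_factory=list)


@dataclass
class AromaticManager:
    """Library of aromatic fragments, deduplicated by canonical identifier."""

    fragments: list[AromaticSubstructure] = field(default_factory=list)
    node_budget: int = DEFAULT_NODE_BUDGET

    def add_fragment(self, fragment: Compound, provenance: str) -> bool:
        """Add a fragment unless an identifier-equal one is already stored."""
        ident = compound_identifier(fragment)
        for existing in self.fragments:
            if existing.identifier == ident:
                if provenance not in existing.provenance:
                    existing.provenance.append(provenance)
                return False
        self.fragments.append(AromaticSubstructure(fragment, ident, [provenance]))
        return True

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        recs = []
        for fr in self.fragments:
            c = fr.fragment
            recs.append({
                "identifier": fr.identifier,
                "atoms": [{"element": a.element, "is_R": a.is_R, "charge": a.charge,
                           "kcf_type": a.kcf_type} for a in c.atoms],
                "bonds": [[b.first_atom, b.second_atom, b.order] for b in c.bonds],
                "provenance": sorted(fr.provenance),
            })
        return json.dumps({"fragments": recs}, indent=2, sort_keys=True) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "AromaticManager":
        data = json.loads(text)
        mgr = cls()
        for k, rec in enumerate(data["fragments"]):
            atoms = [Atom(index=i, element=a["element"], is_R=a["is_R"],
                          charge=a.get("charge", 0), kcf_type=a.get("kcf_type"))
                     for i, a in enumerate(rec["atoms"])]
            bonds = [Bond(i, j, o) for i, j, o in rec["bonds"]]
            frag = Compound(id=f"fragment_{k}", atoms=atoms, bonds=bonds, source="synthetic")
            sub = AromaticSubstructure(frag, rec["identifier"], list(rec["provenance"]))
            mgr.fragments.append(sub)
        return mgr


def extract_from_kcf(compounds: Iterable[Compound],
                     aromatic_types: Iterable[str] = DEFAULT_AROMATIC_TYPES,
                     node_budget: int = DEFAULT_NODE_BUDGET) -> AromaticManager:
    """Build a fragment library from KCF-parsed compounds.

    Atoms whose KCF type is in ``aromatic_types`` are selected; each
    connected component of the induced subgraph becomes a candidate
    fragment, and fragments are deduplicated by identifier across the whole
    corpus.
    """
    types = set(aromatic_types)
    mgr = AromaticManager(node_budget=node_budget)
    for c in compounds:
        selected = [a.index for a in c.atoms if a.kcf_type in types]
        for comp in _components(c, selected):
            frag = _induced_subgraph(c, comp)
            if not all(detect_rings(frag)):
                # stray aromatic-typed atoms outside a closed ring system are
                # annotation noise, not a usable fragment
                logger.warning("discarding non-ring aromatic component of %s (%d atoms)",
                               c.id, frag.n_atoms)
                continue
            mgr.add_fragment(frag, provenance=c.id)
    return mgr


def _components(c: Compound, selected: list[int]) -> list[list[int]]:
    sel = set(selected)
    seen: set[int] = set()
    comps = []
    for start in selected:
        if start in seen:
            continue
        comp = []
        stack = [start]
        seen.add(start)
        while stack:
            v = stack.pop()
            comp.append(v)
            for w, _ in c.neighbors(v):
                if w in sel and w not in seen:
                    seen.add(w)
                    stack.append(w)
        comps.append(sorted(comp))
    return comps


def _induced_subgraph(c: Compound, atom_indices: list[int]) -> Compound:
    remap = {old: new for new, old in enumerate(atom_indices)}
    atoms = []
    for old in atom_indices:
        a = c.atoms[old]
        atoms.append(Atom(index=remap[old], element=a.element, is_R=a.is_R,
                          charge=a.charge, kcf_type=a.kcf_type))
    bonds = [Bond(remap[b.first_atom], remap[b.second_atom], b.order)
             for b in c.bonds
             if b.first_atom in remap and b.second_atom in remap]
    return Compound(id=f"{c.id}_fragment", atoms=atoms, bonds=bonds, source="synthetic")


def detect_aromatic_substructures(c: Compound, mgr: AromaticManager) -> list[set[int]]:
    """Locate library fragments in a compound; returns maximal matched atom sets.

    Fragments are tried largest first so fused systems prefer one large
    match; every complete embedding contributes its target atom set, and
    overlapping sets are merged.  Each fragment search runs under the
    manager's node budget and is abandoned (with a warning) if exceeded.
    """
    detect_rings(c)
    matched_sets: list[set[int]] = []
    for fr in sorted(mgr.fragments, key=lambda f: -f.fragment.n_atoms):
        if fr.fragment.n_atoms > c.n_atoms:
            continue
        opts = MatchOptions.for_aromatic(max_nodes=mgr.node_budget)
        res = find_mappings(fr.fragment, c, opts)
        if res.aborted:
            logger.warning("aromatic search aborted at node budget %d for fragment %s in %s",
                           mgr.node_budget, fr.identifier[:40], c.id)
        for mp in res.mappings:
            matched_sets.append(set(mp.values()))
    return _merge_overlapping(matched_sets)


def _merge_overlapping(sets: list[set[int]]) -> list[set[int]]:
    merged: list[set[int]] = []
    for s in sets:
        absorbed = set(s)
        keep = []
        for t in merged:
            if t & absorbed:
                absorbed |= t
            else:
                keep.append(t)
        keep.append(absorbed)
        merged = keep
    return sorted(merged, key=lambda s: (sorted(s)))


def apply_aromatic_bonds(c: Compound, matches: list[set[int]]) -> Compound:
    """Rewrite every bond internal to a matched set to aromatic order 4.

    Atom count, element labels and connectivity are untouched; the
    operation is idempotent.  Returns a new compound.
    """
    out = c.copy()
    match_sets = [set(s) for s in matches]
    for b in out.bonds:
        for s in match_sets:
            if b.first_atom in s and b.second_atom in s:
                b.order = 4
                break
    if hasattr(out, "ring_bonds"):
        del out.ring_bonds  # type: ignore[attr-defined]
    return out


def aromatize(c: Compound, mgr: Optional[AromaticManager]) -> Compound:
    """Detect and apply in one step; identity when no manager is supplied."""
    if mgr is None or not mgr.fragments:
        return c.copy()
    return apply_aromatic_bonds(c, detect_aromatic_substructures(c, mgr))
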
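"""Deterministic synthetic fixtures: toy molecules, random graphs, toy databases.

Everything here is a pure function of its seed and parameters, so oracle
suites replay exactly.  The toy molecules are small real chemistries
(acetone, butanone, benzene, ...) written directly as graphs and as
molfile/KCF text; the random generators grow connected, valence-capped
molecular graphs and plant known substructure embeddings for recall tests;
`toy_harmonization_scenario` is a miniature two-database snapshot with
hand-constructed ground truth for end-to-end harmonization and auditing.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from molharm.compound import Atom, Bond, Compound, write_molfile
from molharm.substructure import AtomMapping

VALENCE_CAP = {"C": 4, "N": 3, "O": 2, "S": 2, "P": 5,
               "F": 1, "Cl": 1, "Br": 1, "I": 1}


class GenerationError(RuntimeError):
    """A random-structure spec could not be satisfied within bounded retries."""


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one random compound; same spec + seed => identical output."""

    seed: int
    n_atoms: int
    element_palette: tuple[str, ...] = ("C", "C", "C", "N", "O")
    bond_order_palette: tuple[int, ...] = (1, 1, 1, 2)
    ring_probability: float = 0.15


def simple_compound(cid: str, elements: list[str],
                    bonds: list[tuple[int, int, int]],
                    charges: Optional[dict[int, int]] = None) -> Compound:
    """Build a compound from element symbols and (i, j, order) bond triples."""
    charges = charges or {}
    atoms = [Atom(index=i, element=e, is_R=(e in ("R", "R#", "*", "X")),
                  charge=charges.get(i, 0))
             for i, e in enumerate(elements)]
    return Compound(id=cid, atoms=atoms, bonds=[Bond(i, j, o) for i, j, o in bonds])


# ---------------------------------------------------------------------------
# named toy molecules
# ---------------------------------------------------------------------------

def acetone(cid: str = "acetone") -> Compound:
    # CH3-CO-CH3; atom order C, C(carbonyl), C, O
    return simple_compound(cid, ["C", "C", "C", "O"],
                           [(0, 1, 1), (1, 2, 1), (1, 3, 2)])


def butanone(cid: str = "butanone") -> Compound:
    # CH3-CO-CH2-CH3; atom order C, C(carbonyl), O, C, C
    return simple_compound(cid, ["C", "C", "O", "C", "C"],
                           [(0, 1, 1), (1, 2, 2), (1, 3, 1), (3, 4, 1)])


def propanal(cid: str = "propanal") -> Compound:
    # CH3-CH2-CHO
    return simple_compound(cid, ["C", "C", "C", "O"],
                           [(0, 1, 1), (1, 2, 1), (2, 3, 2)])


def acetyl_r(cid: str = "acetyl_R") -> Compound:
    # R-CO-CH3: generic acetyl compound
    return simple_compound(cid, ["R", "C", "O", "C"],
                           [(0, 1, 1), (1, 2, 2), (1, 3, 1)])


def benzene(cid: str = "benzene", kekulization: int = 0) -> Compound:
    orders = [1, 2] * 3 if kekulization == 0 else [2, 1] * 3
    bonds = [(i, (i + 1) % 6, orders[i]) for i in range(6)]
    return simple_compound(cid, ["C"] * 6, bonds)


def toluene(cid: str = "toluene", kekulization: int = 0) -> Compound:
    ring = benzene(cid, kekulization)
    elements = [a.element for a in ring.atoms] + ["C"]
    bonds = [(b.first_atom, b.second_atom, b.order) for b in ring.bonds] + [(0, 6, 1)]
    return simple_compound(cid, elements, bonds)


def o_xylene(cid: str = "o_xylene", kekulization: int = 0) -> Compound:
    """1,2-dimethylbenzene; its two kekulizations are genuinely non-isomorphic."""
    ring = benzene(cid, kekulization)
    elements = [a.element for a in ring.atoms] + ["C", "C"]
    bonds = [(b.first_atom, b.second_atom, b.order) for b in ring.bonds]
    bonds += [(0, 6, 1), (1, 7, 1)]
    return simple_compound(cid, elements, bonds)


def cyclopropane(cid: str = "cyclopropane") -> Compound:
    return simple_compound(cid, ["C"] * 3, [(0, 1, 1), (1, 2, 1), (2, 0, 1)])


def propane(cid: str = "propane") -> Compound:
    return simple_compound(cid, ["C"] * 3, [(0, 1, 1), (1, 2, 1)])


def cyclohexane(cid: str = "cyclohexane") -> Compound:
    return simple_compound(cid, ["C"] * 6, [(i, (i + 1) % 6, 1) for i in range(6)])


def methanol(cid: str = "methanol") -> Compound:
    return simple_compound(cid, ["C", "O"], [(0, 1, 1)])


# ---------------------------------------------------------------------------
# text-format fixtures
# ---------------------------------------------------------------------------

def acetone_molfile(with_hydrogens: bool = False) -> str:
    """A hand-written V2000 acetone record, optionally with explicit hydrogens."""
    heavy = [("C", -1.0, 0.5), ("C", 0.0, 0.0), ("C", 1.0, 0.5), ("O", 0.0, -1.0)]
    hs = [("H", -1.5, 1.0), ("H", -1.5, 0.0), ("H", -0.6, 1.2),
          ("H", 1.5, 1.0), ("H", 1.5, 0.0), ("H", 0.6, 1.2)]
    atoms = heavy + (hs if with_hydrogens else [])
    bonds = [(1, 2, 1), (2, 3, 1), (2, 4, 2)]
    if with_hydrogens:
        bonds += [(1, 5, 1), (1, 6, 1), (1, 7, 1), (3, 8, 1), (3, 9, 1), (3, 10, 1)]
    lines = ["acetone", "  fixture", ""]
    lines.append(f"{len(atoms):3d}{len(bonds):3d}  0  0  0  0  0  0  0  0999 V2000")
    for el, x, y in atoms:
        lines.append(f"{x:10.4f}{y:10.4f}{0.0:10.4f} {el:<3s} 0  0  0  0  0  0  0  0  0  0  0  0")
    for i, j, o in bonds:
        lines.append(f"{i:3d}{j:3d}{o:3d}  0")
    lines.append("M  END")
    return "\n".join(lines) + "\n"


def _kcf_text(entry: str, atoms: list[tuple[str, str, float, float]],
              bonds: list[tuple[int, int, int]]) -> str:
    lines = [f"ENTRY       {entry:<28s}Compound"]
    lines.append(f"ATOM        {len(atoms)}")
    for k, (kcf_type, element, x, y) in enumerate(atoms, start=1):
        lines.append(f"            {k:<3d} {kcf_type:<3s} {element:<2s} {x:8.4f} {y:8.4f}")
    lines.append(f"BOND        {len(bonds)}")
    for k, (i, j, o) in enumerate(bonds, start=1):
        lines.append(f"            {k:<3d} {i:3d} {j:3d} {o}")
    lines.append("///")
    return "\n".join(lines) + "\n"


def benzene_kcf(entry: str = "C_benzene") -> str:
    """Benzene as a KCF record with aromatic carbon types (C8x) and kekulized bonds."""
    atoms = [("C8x", "C", float(k), 0.0) for k in range(6)]
    bonds = [(k + 1, (k + 1) % 6 + 1, 1 + k % 2) for k in range(6)]
    return _kcf_text(entry, atoms, bonds)


def pyridine_kcf(entry: str = "C_pyridine") -> str:
    atoms = [("N5x", "N", 0.0, 0.0)] + [("C8x", "C", float(k), 0.0) for k in range(1, 6)]
    bonds = [(k + 1, (k + 1) % 6 + 1, 1 + k % 2) for k in range(6)]
    return _kcf_text(entry, atoms, bonds)


def naphthalene_kcf(entry: str = "C_naphthalene") -> str:
    """Fused two-ring aromatic system, all 10 atoms aromatic-typed."""
    atoms = [("C8y" if k in (0, 5) else "C8x", "C", float(k), 0.0) for k in range(10)]
    # ring 1: 0-1-2-3-4-5, ring 2: 0-5-6-7-8-9 (fusion bond 0-5)
    edges = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 0),
             (5, 6), (6, 7), (7, 8), (8, 9), (9, 0)]
    orders = [1, 2, 1, 2, 1, 2, 1, 2, 1, 2, 1]
    bonds = [(i + 1, j + 1, o) for (i, j), o in zip(edges, orders)]
    return _kcf_text(entry, atoms, bonds)


def glycine_r_kcf(entry: str = "C_glycineR") -> str:
    """A generic KCF compound: R-CH2-COOH with an R-typed atom."""
    atoms = [("R", "R", 0.0, 0.0), ("C1b", "C", 1.0, 0.0), ("C6a", "C", 2.0, 0.0),
             ("O6a", "O", 3.0, 0.5), ("O6a", "O", 3.0, -0.5)]
    bonds = [(1, 2, 1), (2, 3, 1), (3, 4, 2), (3, 5, 1)]
    return _kcf_text(entry, atoms, bonds)


# ---------------------------------------------------------------------------
# random generators
# ---------------------------------------------------------------------------

def _remaining_valence(c_elements: list[str], degree_orders: list[int], i: int) -> int:
    cap = VALENCE_CAP.get(c_elements[i], 4)
    return cap - degree_orders[i]


def random_compound(spec: FixtureSpec) -> Compound:
    """Grow a connected random molecular graph: spanning tree + ring closures.

    Bond orders count toward a per-element valence cap (C 4, N 3, O 2).
    Bounded retries re-draw the element assignment when the spec cannot be
    satisfied (e.g. an all-oxygen palette with many atoms).
    """
    if spec.n_atoms < 1:
        raise GenerationError("n_atoms must be >= 1")
    rng = random.Random(spec.seed)
    for _attempt in range(50):
        elements = [rng.choice(spec.element_palette) for _ in range(spec.n_atoms)]
        degree = [0] * spec.n_atoms
        bonds: list[tuple[int, int, int]] = []
        ok = True
        for i in range(1, spec.n_atoms):
            candidates = [j for j in range(i) if _remaining_valence(elements, degree, j) >= 1
                          and _remaining_valence(elements, degree, i) >= 1]
            if not candidates:
                ok = False
                break
            j = rng.choice(candidates)
            max_order = min(_remaining_valence(elements, degree, i),
                            _remaining_valence(elements, degree, j))
            order = min(rng.choice(spec.bond_order_palette), max_order)
            bonds.append((j, i, order))
            degree[i] += order
            degree[j] += order
        if not ok:
            continue
        bonded = {frozenset((i, j)) for i, j, _ in bonds}
        for i in range(spec.n_atoms):
            for j in range(i + 1, spec.n_atoms):
                if frozenset((i, j)) in bonded:
                    continue
                if rng.random() >= spec.ring_probability:
                    continue
                if (_remaining_valence(elements, degree, i) >= 1
                        and _remaining_valence(elements, degree, j) >= 1):
                    bonds.append((i, j, 1))
                    bonded.add(frozenset((i, j)))
                    degree[i] += 1
                    degree[j] += 1
        return simple_compound(f"random_{spec.seed}", elements, bonds)
    raise GenerationError(f"could not satisfy {spec} after 50 retries")


def embed_substructure(a: Compound, extra_atoms: int, seed: int,
                       element_palette: tuple[str, ...] = ("C", "C", "N", "O"),
                       ) -> tuple[Compound, AtomMapping]:
    """Plant `a` verbatim inside a larger compound; the identity map is ground truth.

    Extra atoms attach by single bonds to atoms with spare valence (earlier
    extras included), so the original structure is a subgraph of the result
    and the mapping {i: i} is always a valid embedding witness.
    """
    rng = random.Random(seed)
    elements = [x.element for x in a.atoms]
    degree = [0] * a.n_atoms
    bonds = [(b.first_atom, b.second_atom, b.order) for b in a.bonds]
    for i, j, o in bonds:
        degree[i] += o
        degree[j] += o
    for _ in range(extra_atoms):
        el = rng.choice(element_palette)
        elements.append(el)
        degree.append(0)
        new = len(elements) - 1
        hosts = [j for j in range(new) if _remaining_valence(elements, degree, j) >= 1]
        if not hosts:
            hosts = [new - 1]  # degenerate saturated case: still attach (graph fixture)
        j = rng.choice(hosts)
        bonds.append((j, new, 1))
        degree[j] += 1
        degree[new] += 1
    b = simple_compound(f"{a.id}_embedded_{seed}", elements, bonds)
    planted: AtomMapping = {i: i for i in range(a.n_atoms) if not a.atoms[i].is_R}
    return b, planted


def random_pattern_target_pair(seed: int, planted: bool,
                               n_pattern: int = 5, n_extra: int = 4,
                               ) -> tuple[Compound, Compound]:
    """A (pattern, target) pair: target either embeds the pattern or is independent."""
    a = random_compound(FixtureSpec(seed=seed * 2 + 1, n_atoms=n_pattern))
    if planted:
        b, _ = embed_substructure(a, n_extra, seed=seed * 2 + 2)
    else:
        b = random_compound(FixtureSpec(seed=seed * 2 + 2, n_atoms=n_pattern + n_extra))
    return a, b


# ---------------------------------------------------------------------------
# toy two-database scenario
# ---------------------------------------------------------------------------

def toy_harmonization_scenario():
    """Fixed miniature of a two-snapshot harmonization study.

    Returns ``(dbA, dbB, ref_pairs, expected_edges, expected_audit)``:
    dbA holds acetone, benzene and a generic acetyl compound; dbB holds
    acetone, 2-butanone, an alternately kekulized benzene, a broken record
    with no parsable structure, and propanal (same formula as acetone,
    different structure).  Ground truth: 2 exact edges + 2 generic edges;
    the four reference pairs audit to one of each category.
    """
    dbA: dict[str, Optional[Compound]] = {
        "A_acetone": acetone("A_acetone"),
        "A_benzene": benzene("A_benzene", kekulization=0),
        "A_acetylR": acetyl_r("A_acetylR"),
    }
    dbB: dict[str, Optional[Compound]] = {
        "B_acetone": acetone("B_acetone"),
        "B_butanone": butanone("B_butanone"),
        "B_benzene": benzene("B_benzene", kekulization=1),
        "B_broken": None,
        "B_propanal": propanal("B_propanal"),
    }
    ref_pairs = [
        ("B_acetone", "A_acetone"),    # validated by harmonization
        ("B_broken", "A_benzene"),     # remote structure unparsable
        ("B_butanone", "A_acetone"),   # C4O vs C3O: inconsistent formulas
        ("B_propanal", "A_acetone"),   # same formula, different structure
    ]
    expected_edges = {
        ("A_acetone", "B_acetone", "exact"),
        ("A_benzene", "B_benzene", "exact"),
        ("A_acetylR", "B_acetone", "generic"),
        ("A_acetylR", "B_butanone", "generic"),
    }
    expected_audit = {
        ("B_acetone", "A_acetone"): "validated",
        ("B_broken", "A_benzene"): "invalid_reference",
        ("B_butanone", "A_acetone"): "inconsistent_formula",
        ("B_propanal", "A_acetone"): "other",
    }
    return dbA, dbB, ref_pairs, expected_edges, expected_audit


def emit_database(directory: Path, db: dict[str, Optional[Compound]]) -> None:
    """Write a snapshot as one molfile per compound (broken records as empty files)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for cid, c in sorted(db.items()):
        path = directory / f"{cid}.mol"
        path.write_text("" if c is None else write_molfile(c))


def emit_reactions_tsv(path: Path, reactions) -> None:
    """Write reactions as TSV: id, reactants 'cid:coef;...', products, EC list."""
    def side(parts) -> str:
        return ";".join(f"{cid}:{coef}" for cid, coef in parts)

    lines = [f"{r.id}\t{side(r.reactants)}\t{side(r.products)}\t{','.join(r.ec_numbers)}"
             for r in reactions]
    Path(path).write_text("\n".join(lines) + "\n")
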
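"""Substructure detection: mapping matrix, backtracking search, prunings.

Given a pattern compound A (n atoms) and a target B (m atoms), the search
proceeds in two steps.  First a boolean *mapping matrix* M (n×m) records
which atom pairs are candidate matches under per-atom criteria: same
element, ring membership (a pattern ring atom must map to a target ring
atom), dominance of the pattern atom's per-bond-order counts by the target
atom's, dominance of its per-neighbor-element counts, and — for generic
R-group compounds — equality of the layered atom colors at the level just
below the atom's distance to the nearest R group.  Second, a backtracking
enumeration assigns target atoms to pattern atoms one at a time, checking
bond compatibility against previously assigned neighbors and, optionally,
the shortest-distance pruning rule

    D_A[i][k] >= D_B[map(i)][map(k)]   for every earlier assigned atom k,

which is valid because extending a structure with new atoms or bonds can
never lengthen a shortest path.  All per-atom criteria and both prunings
are necessary conditions for a complete embedding, so they shrink the
search space without changing the result set.

A deliberately naive exhaustive enumerator (`brute_force_mappings`) serves
as the testing ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from molharm.compound import Compound, ring_bond_set
from molharm.coloring import AtomColorTable, atom_colors, color_at_level
from molharm.graph_metrics import all_pairs_shortest_distance, distance_to_R

AtomMapping = dict[int, int]  # pattern atom index -> target atom index


@dataclass(frozen=True)
class MatchOptions:
    """Criteria and pruning switches for one substructure search.

    The default profile is the full search used for plain (non-generic)
    substructure containment; `for_generic()` and `for_aromatic()` build the
    profiles used by harmonization and aromatic detection.
    """

    same_element: bool = True
    ring_forward: bool = True            # pattern atom in ring => target atom in ring
    bond_count_dominance: bool = True    # per-bond-order counts dominated
    atom_neighbor_dominance: bool = True # per-neighbor-element counts dominated
    color_level_check: bool = False      # generic pairs: colors equal at level d_R - 1
    distance_pruning: bool = True        # shortest-distance rule on partial mappings
    aromatic_tolerant: bool = False      # pool orders {2,4} on ring bonds
    skip_pattern_r: bool = True          # R atoms of the pattern carry no row constraint
    order: str = "index"                 # pattern visit order: "index" or "rarest"
    max_nodes: Optional[int] = None      # node-budget cap; None = unlimited

    @staticmethod
    def for_generic() -> "MatchOptions":
        return MatchOptions(color_level_check=True)

    @staticmethod
    def for_aromatic(max_nodes: Optional[int] = 10 ** 6) -> "MatchOptions":
        return MatchOptions(aromatic_tolerant=True, max_nodes=max_nodes)

    @staticmethod
    def baseline() -> "MatchOptions":
        """The three per-atom criteria only; no dominance or distance prunings."""
        return MatchOptions(atom_neighbor_dominance=False, distance_pruning=False)


@dataclass
class MappingMatrix:
    """Boolean candidate table plus the pattern atoms actually constrained."""

    M: np.ndarray                 # n×m boolean
    pattern_atoms: list[int]      # pattern atoms participating in the mapping
    options: MatchOptions

    def infeasible(self) -> bool:
        """True when some constrained pattern atom has no candidate at all."""
        return any(not self.M[i].any() for i in self.pattern_atoms)


@dataclass
class SearchResult:
    """Mappings found plus search-effort accounting."""

    mappings: list[AtomMapping] = field(default_factory=list)
    expanded_nodes: int = 0
    aborted: bool = False          # node budget exhausted before completion

    def serialized(self, n_pattern: int) -> list[list[int]]:
        out = []
        for mp in self.mappings:
            out.append([mp.get(i, -1) for i in range(n_pattern)])
        return out


def _bond_in_ring(c: Compound, i: int, j: int) -> bool:
    return frozenset((i, j)) in ring_bond_set(c)


def _pooled_order(order: int, in_ring: bool, aromatic_tolerant: bool):
    if aromatic_tolerant and in_ring and order in (2, 4):
        return "ar"
    return order


def _bonds_compatible(oa: int, ob: int, ring_a: bool, ring_b: bool,
                      aromatic_tolerant: bool) -> bool:
    if oa == ob:
        return True
    return (aromatic_tolerant and ring_a and ring_b
            and oa in (2, 4) and ob in (2, 4))


def _atom_features(c: Compound, exclude_r_neighbors: bool, aromatic_tolerant: bool):
    """Per-atom (bond-order counts, neighbor-element counts) with optional pooling."""
    ring_bonds = ring_bond_set(c)
    bond_counts: list[dict] = []
    elem_counts: list[dict] = []
    for i in range(c.n_atoms):
        bc: dict = {}
        ec: dict = {}
        for j, order in c.neighbors(i):
            if exclude_r_neighbors and c.atoms[j].is_R:
                continue
            key = _pooled_order(order, frozenset((i, j)) in ring_bonds, aromatic_tolerant)
            bc[key] = bc.get(key, 0) + 1
            el = "R" if c.atoms[j].is_R else c.atoms[j].element
            ec[el] = ec.get(el, 0) + 1
        bond_counts.append(bc)
        elem_counts.append(ec)
    return bond_counts, elem_counts


def _dominates(small: dict, big: dict) -> bool:
    return all(big.get(k, 0) >= v for k, v in small.items())


def build_mapping_matrix(A: Compound, B: Compound, opts: MatchOptions,
                         colors_a: Optional[AtomColorTable] = None,
                         colors_b: Optional[AtomColorTable] = None,
                         DR_A: Optional[np.ndarray] = None) -> MappingMatrix:
    """Construct the candidate matrix between pattern A and target B.

    When `color_level_check` is enabled the two color tables and the
    pattern's R-distance array must be supplied; the check compares the two
    atoms' colors at level ``d_R - 1`` for pattern atoms with a finite,
    positive distance ``d_R`` to the nearest R group (those colors depend
    only on atoms strictly closer than the R boundary, so a generic compound
    and its specific counterpart agree on them).
    """
    if opts.color_level_check and (colors_a is None or colors_b is None or DR_A is None):
        raise ValueError("color_level_check requires colors_a, colors_b and DR_A")

    n, m = A.n_atoms, B.n_atoms
    ring_a = [a.in_ring for a in A.atoms] if _ensure_rings(A) else []
    ring_b = [a.in_ring for a in B.atoms] if _ensure_rings(B) else []
    bcA, ecA = _atom_features(A, exclude_r_neighbors=opts.skip_pattern_r,
                              aromatic_tolerant=opts.aromatic_tolerant)
    bcB, ecB = _atom_features(B, exclude_r_neighbors=False,
                              aromatic_tolerant=opts.aromatic_tolerant)

    pattern_atoms = [a.index for a in A.atoms if not (opts.skip_pattern_r and a.is_R)]
    M = np.zeros((n, m), dtype=bool)
    sentinel_a = n
    for i in pattern_atoms:
        ai = A.atoms[i]
        for j in range(m):
            bj = B.atoms[j]
            if opts.same_element and (ai.element != bj.element or ai.is_R != bj.is_R):
                continue
            if opts.ring_forward and ring_a[i] and not ring_b[j]:
                continue
            if opts.bond_count_dominance and not _dominates(bcA[i], bcB[j]):
                continue
            if opts.atom_neighbor_dominance and not _dominates(ecA[i], ecB[j]):
                continue
            if opts.color_level_check:
                d_r = int(DR_A[i])
                if 1 <= d_r < sentinel_a:
                    if (color_at_level(colors_a, i, d_r - 1)
                            != color_at_level(colors_b, j, d_r - 1)):
                        continue
            M[i, j] = True
    return MappingMatrix(M=M, pattern_atoms=pattern_atoms, options=opts)


def _ensure_rings(c: Compound) -> bool:
    ring_bond_set(c)  # runs perception once, cached
    return True


def backtrack_mappings(A: Compound, B: Compound, matrix: MappingMatrix,
                       D_A: Optional[np.ndarray] = None,
                       D_B: Optional[np.ndarray] = None,
                       opts: Optional[MatchOptions] = None,
                       stop_after_first: bool = False) -> SearchResult:
    """Enumerate every complete injective pattern-into-target mapping.

    Pattern atoms are visited in ascending index order by default (or
    rarest-candidate-first with ``order="rarest"``); candidates for each
    atom are scanned in ascending target index, and on exhaustion the search
    backtracks to the previous atom and resumes from its next candidate.
    Every saved mapping maps each bonded pattern pair onto a compatibly
    bonded target pair.  The search keeps going after each hit, so the
    result holds *all* embeddings; `expanded_nodes` counts candidate
    assignments examined.
    """
    opts = opts if opts is not None else matrix.options
    if opts.distance_pruning and (D_A is None or D_B is None):
        raise ValueError("distance_pruning requires both distance matrices")

    pattern = list(matrix.pattern_atoms)
    if opts.order == "rarest":
        pattern.sort(key=lambda i: (int(matrix.M[i].sum()), i))
    p = len(pattern)
    m = B.n_atoms
    result = SearchResult()
    if p == 0:
        result.mappings.append({})
        return result
    if matrix.infeasible() or p > m:
        return result

    adjA = {i: [(j, o) for j, o in A.neighbors(i)] for i in pattern}
    ringA = ring_bond_set(A)
    ringB = ring_bond_set(B)
    sentinel_a = A.n_atoms

    pos_of = {atom: pos for pos, atom in enumerate(pattern)}
    o2om = [-1] * p          # target index per pattern position
    used = [False] * m
    cursor = [0] * p         # next candidate target index to try at each position
    pos = 0
    while pos >= 0:
        if opts.max_nodes is not None and result.expanded_nodes >= opts.max_nodes:
            result.aborted = True
            break
        i = pattern[pos]
        found = False
        j = cursor[pos]
        while j < m:
            if matrix.M[i, j] and not used[j]:
                result.expanded_nodes += 1
                if _consistent(A, B, adjA, ringA, ringB, pattern, pos_of, o2om,
                               pos, i, j, D_A, D_B, sentinel_a, opts):
                    found = True
                    break
            j += 1
        if found:
            o2om[pos] = j
            used[j] = True
            cursor[pos] = j + 1
            if pos == p - 1:
                result.mappings.append({pattern[k]: o2om[k] for k in range(p)})
                if stop_after_first:
                    break
                used[j] = False   # keep searching for further embeddings
                o2om[pos] = -1
            else:
                pos += 1
                cursor[pos] = 0
        else:
            cursor[pos] = 0
            pos -= 1
            if pos >= 0 and o2om[pos] >= 0:
                used[o2om[pos]] = False
                o2om[pos] = -1
    result.mappings.sort(key=lambda mp: [mp[i] for i in sorted(mp)])
    return result


def _consistent(A, B, adjA, ringA, ringB, pattern, pos_of, o2om, pos, i, j,
                D_A, D_B, sentinel_a, opts) -> bool:
    # bond compatibility against previously assigned neighbors of i
    for k, order in adjA[i]:
        kpos = pos_of.get(k)
        if kpos is None or kpos >= pos or o2om[kpos] < 0:
            continue
        jt = o2om[kpos]
        ob = B.bond_order(j, jt)
        if ob == 0:
            return False
        if not _bonds_compatible(order, ob, frozenset((i, k)) in ringA,
                                 frozenset((j, jt)) in ringB, opts.aromatic_tolerant):
            return False
    if opts.distance_pruning:
        for kpos in range(pos):
            if o2om[kpos] < 0:
                continue
            k = pattern[kpos]
            da = int(D_A[i, k])
            if da >= sentinel_a:
                continue  # disconnected in the pattern: no constraint
            if da < int(D_B[j, o2om[kpos]]):
                return False
    return True


def find_mappings(A: Compound, B: Compound, opts: Optional[MatchOptions] = None,
                  stop_after_first: bool = False) -> SearchResult:
    """High-level search: derives rings, colors and distances as the options need."""
    opts = opts if opts is not None else MatchOptions()
    colors_a = colors_b = None
    DR_A = None
    if opts.color_level_check:
        colors_a = atom_colors(A)
        colors_b = atom_colors(B)
        DR_A = distance_to_R(A)
    matrix = build_mapping_matrix(A, B, opts, colors_a, colors_b, DR_A)
    D_A = D_B = None
    if opts.distance_pruning:
        D_A = all_pairs_shortest_distance(A)
        D_B = all_pairs_shortest_distance(B)
    return backtrack_mappings(A, B, matrix, D_A, D_B, opts,
                              stop_after_first=stop_after_first)


def is_substructure(A: Compound, B: Compound,
                    opts: Optional[MatchOptions] = None) -> tuple[bool, Optional[AtomMapping]]:
    """Whether pattern A embeds in target B; returns the first witness mapping."""
    opts = opts if opts is not None else MatchOptions()
    n_constrained = sum(1 for a in A.atoms if not (opts.skip_pattern_r and a.is_R))
    if n_constrained > B.n_atoms:
        return False, None
    res = find_mappings(A, B, opts, stop_after_first=True)
    if res.mappings:
        return True, res.mappings[0]
    return False, None


# ---------------------------------------------------------------------------
# exhaustive oracle
# ---------------------------------------------------------------------------

BRUTE_FORCE_MAX_PATTERN = 8
BRUTE_FORCE_MAX_TARGET = 12


def brute_force_mappings(A: Compound, B: Compound,
                         basic_criteria_only: bool = True,
                         aromatic_tolerant: bool = False,
                         skip_pattern_r: bool = False) -> list[AtomMapping]:
    """Exhaustively enumerate all injective embeddings of A into B.

    Filters only on element equality and exact bond compatibility — no
    ring, dominance, color or distance reasoning — so it is a trustworthy,
    if slow, ground truth for the optimized search.  Guarded to small sizes.
    """
    del basic_criteria_only  # only profile offered; argument kept for clarity at call sites
    pattern = [a.index for a in A.atoms if not (skip_pattern_r and a.is_R)]
    if len(pattern) > BRUTE_FORCE_MAX_PATTERN or B.n_atoms > BRUTE_FORCE_MAX_TARGET:
        raise ValueError(
            f"brute force limited to pattern<={BRUTE_FORCE_MAX_PATTERN}, "
            f"target<={BRUTE_FORCE_MAX_TARGET} atoms")
    ringA = ring_bond_set(A)
    ringB = ring_bond_set(B)
    m = B.n_atoms
    found: list[AtomMapping] = []
    assign: AtomMapping = {}

    def recurse(pos: int) -> None:
        if pos == len(pattern):
            found.append(dict(assign))
            return
        i = pattern[pos]
        ai = A.atoms[i]
        for j in range(m):
            bj = B.atoms[j]
            if j in assign.values():
                continue
            if ai.element != bj.element or ai.is_R != bj.is_R:
                continue
            ok = True
            for k, order in A.neighbors(i):
                if k in assign:
                    ob = B.bond_order(j, assign[k])
                    if ob == 0 or not _bonds_compatible(
                            order, ob, frozenset((i, k)) in ringA,
                            frozenset((j, assign[k])) in ringB, aromatic_tolerant):
                        ok = False
                        break
            if ok:
                assign[i] = j
                recurse(pos + 1)
                del assign[i]

    recurse(0)
    found.sort(key=lambda mp: [mp[i] for i in sorted(mp)])
    return found


def verify_mapping(A: Compound, B: Compound, mapping: AtomMapping,
                   aromatic_tolerant: bool = False) -> bool:
    """Re-validate one mapping from first principles (injectivity, labels, bonds)."""
    if len(set(mapping.values())) != len(mapping):
        return False
    ringA = ring_bond_set(A)
    ringB = ring_bond_set(B)
    for i, j in mapping.items():
        ai, bj = A.atoms[i], B.atoms[j]
        if ai.element != bj.element or ai.is_R != bj.is_R:
            return False
    for b in A.bonds:
        if b.first_atom in mapping and b.second_atom in mapping:
            jt1, jt2 = mapping[b.first_atom], mapping[b.second_atom]
            ob = B.bond_order(jt1, jt2)
            if ob == 0 or not _bonds_compatible(
                    b.order, ob, b.key() in ringA,
                    frozenset((jt1, jt2)) in ringB, aromatic_tolerant):
                return False
    return True
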
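"""Cross-database compound and reaction harmonization and reference auditing.

Two database snapshots are paired at two levels.  *Exact* edges connect
compounds whose canonical identifiers coincide after aromatic curation.
*Generic* edges connect an R-group (generic) compound to a partner that
contains its non-R scaffold as a substructure, provided every unmatched
branch of the partner can be absorbed by one of the generic compound's R
groups.  Reaction edges pair reactions whose participant multisets are in
bijection through compound edges (allowing the reactant/product sides to
swap).  Finally, externally asserted cross-references can be audited
against the harmonized edges and categorized as validated, invalid
reference, inconsistent formula, or other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from molharm.aromatics import AromaticManager, aromatize
from molharm.compound import Compound, element_counts, molecular_formula
from molharm.coloring import compound_identifier
from molharm.substructure import (
    AtomMapping,
    MatchOptions,
    find_mappings,
)


@dataclass
class Reaction:
    """A reaction: participant compound ids with stoichiometric counts, EC numbers."""

    id: str
    reactants: list[tuple[str, int]]
    products: list[tuple[str, int]]
    ec_numbers: list[str] = field(default_factory=list)


@dataclass
class HarmonizedCompoundEdge:
    """Cross-database pairing of two compound records.

    ``mapping`` sends the pattern side's non-R atoms onto the other side's
    atoms; ``pattern_side`` says which side the pattern (more generic
    compound, for generic edges) lives on.  ``r_assignments`` gives, for a
    generic edge, the branch atoms of the specific side absorbed by each R
    atom of the generic side.
    """

    left_db: str
    left_id: str
    right_db: str
    right_id: str
    relationship: str                      # "exact" | "generic"
    mapping: AtomMapping
    pattern_side: str = "left"
    r_assignments: Optional[dict[int, tuple[int, ...]]] = None

    def pair(self) -> tuple[str, str]:
        return (self.left_id, self.right_id)

    def to_json_dict(self) -> dict:
        d = {
            "left_db": self.left_db, "left_id": self.left_id,
            "right_db": self.right_db, "right_id": self.right_id,
            "relationship": self.relationship,
            "pattern_side": self.pattern_side,
            "mapping": {str(k): v for k, v in sorted(self.mapping.items())},
        }
        if self.r_assignments is not None:
            d["r_assignments"] = {str(k): sorted(v)
                                  for k, v in sorted(self.r_assignments.items())}
        return d


@dataclass
class HarmonizedReactionEdge:
    """Cross-database pairing of two reactions via harmonized participants."""

    left_db: str
    left_id: str
    right_db: str
    right_id: str
    swapped_sides: bool
    participant_pairing: list[tuple[str, str]]

    def to_json_dict(self) -> dict:
        return {
            "left_db": self.left_db, "left_id": self.left_id,
            "right_db": self.right_db, "right_id": self.right_id,
            "swapped_sides": self.swapped_sides,
            "participant_pairing": [list(p) for p in self.participant_pairing],
        }


AUDIT_CATEGORIES = ("validated", "invalid_reference", "inconsistent_formula", "other")


@dataclass
class ReferenceAudit:
    """Classification of one asserted cross-reference pair."""

    remote_id: str
    local_id: str
    category: str


# ---------------------------------------------------------------------------
# compound-level matching
# ---------------------------------------------------------------------------

def _bond_order_multiset(c: Compound) -> tuple[tuple[int, int], ...]:
    counts: dict[int, int] = {}
    for b in c.bonds:
        counts[b.order] = counts.get(b.order, 0) + 1
    return tuple(sorted(counts.items()))


def match_exact(a: Compound, b: Compound,
                left_db: str = "A", right_db: str = "B") -> Optional[HarmonizedCompoundEdge]:
    """Exact pairing: equal canonical identifiers (plus a bond-multiset safety net).

    Both compounds should already be aromatized so kekulization variants
    share an identifier.  The atom-level mapping is recovered by a full
    substructure search between the two equal-sized structures.
    """
    if compound_identifier(a) != compound_identifier(b):
        return None
    if _bond_order_multiset(a) != _bond_order_multiset(b):
        return None  # 1-WL safety net: identifiers can collide on regular graphs
    opts = MatchOptions(skip_pattern_r=False)
    res = find_mappings(a, b, opts, stop_after_first=True)
    if not res.mappings:
        return None
    return HarmonizedCompoundEdge(left_db, a.id, right_db, b.id,
                                  relationship="exact", mapping=res.mappings[0])


def map_R_groups(a: Compound, b: Compound,
                 mapping: AtomMapping) -> Optional[dict[int, tuple[int, ...]]]:
    """Assign every unmatched branch of b to an R group of a, or fail.

    The connected components of b's atoms outside the mapping image are the
    candidate branches.  A branch may attach to the image only at atoms
    whose preimage in a is adjacent to some R atom; each branch is assigned
    to the smallest-index such R.  Success requires every outside atom to be
    absorbed.  R atoms left over absorb an empty branch (R may stand for a
    hydrogen).  Failure is returned as ``None``.
    """
    image = set(mapping.values())
    inverse = {v: k for k, v in mapping.items()}
    r_atoms = a.r_atom_indices()

    # image atoms at which branches may legally attach -> adjacent R atoms of a
    eligible: dict[int, list[int]] = {}
    for i, j in mapping.items():
        rs = sorted(k for k, _ in a.neighbors(i) if a.atoms[k].is_R)
        if rs:
            eligible[j] = rs

    outside = [idx for idx in range(b.n_atoms) if idx not in image]
    assignments: dict[int, set[int]] = {r: set() for r in r_atoms}
    seen: set[int] = set()
    for start in outside:
        if start in seen:
            continue
        comp = []
        attach_points: set[int] = set()
        stack = [start]
        seen.add(start)
        while stack:
            v = stack.pop()
            comp.append(v)
            for w, _ in b.neighbors(v):
                if w in image:
                    attach_points.add(w)
                elif w not in seen:
                    seen.add(w)
                    stack.append(w)
        if not attach_points:
            return None  # floating extra component: no R can absorb it
        if any(p not in eligible for p in attach_points):
            return None  # attaches where the pattern has no adjacent R group
        candidates = sorted({r for p in attach_points for r in eligible[p]})
        assignments[candidates[0]].update(comp)
    del inverse
    return {r: tuple(sorted(v)) for r, v in assignments.items()}


def match_generic(a: Compound, b: Compound,
                  left_db: str = "A", right_db: str = "B") -> Optional[HarmonizedCompoundEdge]:
    """Generic pairing: a's non-R scaffold embeds in b and R groups absorb the rest.

    ``a`` must be the more generic side (contain at least one R atom).  The
    search uses the color-at-level-(d_R - 1) criterion together with the
    dominance and distance prunings; the first witness whose unmatched
    branches pass R-group coverage wins, and all remaining witnesses are
    still enumerated internally in deterministic order.
    """
    if not a.r_atom_indices():
        return None
    opts = MatchOptions.for_generic()
    res = find_mappings(a, b, opts)
    for mp in res.mappings:
        r_assign = map_R_groups(a, b, mp)
        if r_assign is not None:
            return HarmonizedCompoundEdge(left_db, a.id, right_db, b.id,
                                          relationship="generic", mapping=mp,
                                          r_assignments=r_assign)
    return None


# ---------------------------------------------------------------------------
# database-level harmonization
# ---------------------------------------------------------------------------

def _dominates_counts(small: Mapping[str, int], big: Mapping[str, int]) -> bool:
    return all(big.get(k, 0) >= v for k, v in small.items())


def harmonize_compound_databases(dbA: Mapping[str, Optional[Compound]],
                                 dbB: Mapping[str, Optional[Compound]],
                                 mgr: Optional[AromaticManager] = None,
                                 db_names: tuple[str, str] = ("A", "B"),
                                 ) -> list[HarmonizedCompoundEdge]:
    """Pair all compounds of two snapshots: exact first, then generic.

    All structures are aromatized with the supplied manager.  Exact matching
    only compares compounds within equal-formula buckets; generic matching
    tries every R-containing compound against partners whose element counts
    dominate its non-R counts (in both directions when both sides carry R
    groups, the less generic side serving as target).  Records without a
    parsable structure are skipped.  Output is sorted by id pair for
    deterministic serialization.
    """
    name_a, name_b = db_names
    prepared_a = {cid: aromatize(c, mgr) for cid, c in sorted(dbA.items()) if c is not None}
    prepared_b = {cid: aromatize(c, mgr) for cid, c in sorted(dbB.items()) if c is not None}

    edges: list[HarmonizedCompoundEdge] = []
    paired: set[tuple[str, str]] = set()

    buckets_b: dict[str, list[str]] = {}
    for cid, c in prepared_b.items():
        buckets_b.setdefault(molecular_formula(c), []).append(cid)

    for cid_a, ca in prepared_a.items():
        for cid_b in buckets_b.get(molecular_formula(ca), []):
            edge = match_exact(ca, prepared_b[cid_b], name_a, name_b)
            if edge is not None:
                edges.append(edge)
                paired.add(edge.pair())

    counts_b = {cid: element_counts(c) for cid, c in prepared_b.items()}
    counts_a = {cid: element_counts(c) for cid, c in prepared_a.items()}
    for cid_a, ca in prepared_a.items():
        if not ca.r_atom_indices():
            continue
        need = element_counts(ca)  # non-R counts of the generic side
        for cid_b, cb in prepared_b.items():
            if (cid_a, cid_b) in paired:
                continue
            if not _dominates_counts(need, counts_b[cid_b]):
                continue
            edge = match_generic(ca, cb, name_a, name_b)
            if edge is not None:
                edges.append(edge)
                paired.add(edge.pair())
    # both-generic or right-side-generic pairs: pattern on the right
    for cid_b, cb in prepared_b.items():
        if not cb.r_atom_indices():
            continue
        need = element_counts(cb)
        for cid_a, ca in prepared_a.items():
            if (cid_a, cid_b) in paired:
                continue
            if not _dominates_counts(need, counts_a[cid_a]):
                continue
            edge = match_generic(cb, ca, name_b, name_a)
            if edge is not None:
                edges.append(HarmonizedCompoundEdge(
                    name_a, cid_a, name_b, cid_b, relationship="generic",
                    mapping=edge.mapping, pattern_side="right",
                    r_assignments=edge.r_assignments))
                paired.add((cid_a, cid_b))
    edges.sort(key=lambda e: (e.left_id, e.right_id, e.relationship))
    return edges


def _bijection_exists(left: list[tuple[str, int]], right: list[tuple[str, int]],
                      compatible, require_stoich: bool) -> Optional[list[tuple[str, str]]]:
    if len(left) != len(right):
        return None
    used = [False] * len(right)
    pairing: list[tuple[str, str]] = []

    def recurse(pos: int) -> bool:
        if pos == len(left):
            return True
        lid, lcoef = left[pos]
        for k, (rid, rcoef) in enumerate(right):
            if used[k]:
                continue
            if require_stoich and lcoef != rcoef:
                continue
            if not compatible(lid, rid):
                continue
            used[k] = True
            pairing.append((lid, rid))
            if recurse(pos + 1):
                return True
            used[k] = False
            pairing.pop()
        return False

    return pairing if recurse(0) else None


def _ec_compatible(a: Reaction, b: Reaction) -> bool:
    if not a.ec_numbers or not b.ec_numbers:
        return True  # soft filter: only applies when both sides annotate EC
    first = {e.split(".")[0] for e in a.ec_numbers}
    return any(e.split(".")[0] in first for e in b.ec_numbers)


def harmonize_reaction_databases(rdbA: Iterable[Reaction], rdbB: Iterable[Reaction],
                                 compound_edges: Iterable[HarmonizedCompoundEdge],
                                 require_stoich: bool = True,
                                 check_ec: bool = True,
                                 db_names: tuple[str, str] = ("A", "B"),
                                 ) -> list[HarmonizedReactionEdge]:
    """Pair reactions whose participants biject through compound edges.

    The reactant/product sides may swap as a whole (a reaction written in
    the reverse direction still pairs).  Identical compound ids count as
    trivially harmonized.  Stoichiometric coefficients must agree exactly
    unless ``require_stoich`` is off; EC numbers, when present on both
    sides, must share a top-level class unless ``check_ec`` is off.
    """
    pairs = {(e.left_id, e.right_id) for e in compound_edges}

    def compatible(lid: str, rid: str) -> bool:
        return lid == rid or (lid, rid) in pairs

    out: list[HarmonizedReactionEdge] = []
    for ra in rdbA:
        for rb in rdbB:
            if check_ec and not _ec_compatible(ra, rb):
                continue
            forward_r = _bijection_exists(ra.reactants, rb.reactants, compatible, require_stoich)
            forward_p = (_bijection_exists(ra.products, rb.products, compatible, require_stoich)
                         if forward_r is not None else None)
            if forward_r is not None and forward_p is not None:
                out.append(HarmonizedReactionEdge(db_names[0], ra.id, db_names[1], rb.id,
                                                  swapped_sides=False,
                                                  participant_pairing=forward_r + forward_p))
                continue
            swapped_r = _bijection_exists(ra.reactants, rb.products, compatible, require_stoich)
            swapped_p = (_bijection_exists(ra.products, rb.reactants, compatible, require_stoich)
                         if swapped_r is not None else None)
            if swapped_r is not None and swapped_p is not None:
                out.append(HarmonizedReactionEdge(db_names[0], ra.id, db_names[1], rb.id,
                                                  swapped_sides=True,
                                                  participant_pairing=swapped_r + swapped_p))
    out.sort(key=lambda e: (e.left_id, e.right_id))
    return out


# ---------------------------------------------------------------------------
# reference auditing
# ---------------------------------------------------------------------------

def categorize_reference_pairs(ref_pairs: Iterable[tuple[str, str]],
                               db_local: Mapping[str, Optional[Compound]],
                               db_remote: Mapping[str, Optional[Compound]],
                               edges: Iterable[HarmonizedCompoundEdge],
                               ) -> tuple[list[ReferenceAudit], dict]:
    """Audit asserted cross-references (remote id, local id) against edges.

    Decision order per pair: (1) the remote record is absent or has no
    parsable structure -> invalid_reference; (2) the pair appears among the
    harmonized edges (either orientation) -> validated; (3) the heavy-atom
    formulas differ -> inconsistent_formula; (4) otherwise -> other.
    The summary reports per-category counts and, for the three missed
    categories, percentages of the missed total.
    """
    edge_pairs = set()
    for e in edges:
        edge_pairs.add((e.left_id, e.right_id))
        edge_pairs.add((e.right_id, e.left_id))

    audits: list[ReferenceAudit] = []
    for remote_id, local_id in ref_pairs:
        remote = db_remote.get(remote_id)
        local = db_local.get(local_id)
        if remote is None:
            category = "invalid_reference"
        elif (remote_id, local_id) in edge_pairs or (local_id, remote_id) in edge_pairs:
            category = "validated"
        elif local is None:
            category = "other"
        elif molecular_formula(remote) != molecular_formula(local):
            category = "inconsistent_formula"
        else:
            category = "other"
        audits.append(ReferenceAudit(remote_id, local_id, category))

    counts = {cat: sum(1 for a in audits if a.category == cat) for cat in AUDIT_CATEGORIES}
    summary = audit_summary(counts["invalid_reference"], counts["inconsistent_formula"],
                            counts["other"])
    summary["validated"] = counts["validated"]
    summary["n_pairs"] = len(audits)
    return audits, summary


def audit_summary(invalid: int, inconsistent: int, other: int) -> dict:
    """Missed-pair category summary: counts and percentages of the missed total.

    Percentages are rounded half-up to two decimals.
    """
    total = invalid + inconsistent + other

    def pct(x: int) -> float:
        if total == 0:
            return 0.0
        return float(round(100.0 * x / total + 1e-9, 2))

    return {
        "invalid_reference": invalid,
        "inconsistent_formula": inconsistent,
        "other": other,
        "missed_total": total,
        "invalid_reference_pct": pct(invalid),
        "inconsistent_formula_pct": pct(inconsistent),
        "other_pct": pct(other),
    }
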
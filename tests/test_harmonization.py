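"""Compound/reaction harmonization and cross-reference auditing."""

from molharm.aromatics import extract_from_kcf
from molharm.compound import parse_kcf
from molharm.fixtures import (
    acetone,
    acetyl_r,
    benzene,
    benzene_kcf,
    butanone,
    propanal,
    simple_compound,
)
from molharm.harmonization import (
    Reaction,
    audit_summary,
    categorize_reference_pairs,
    harmonize_compound_databases,
    harmonize_reaction_databases,
    map_R_groups,
    match_exact,
    match_generic,
)
from molharm.substructure import verify_mapping


class TestMatchExact:
    def test_same_structure_different_ids(self):
        edge = match_exact(acetone("id1"), acetone("id2"))
        assert edge is not None and edge.relationship == "exact"
        assert verify_mapping(acetone("id1"), acetone("id2"), edge.mapping)

    def test_different_compounds_do_not_pair(self):
        assert match_exact(acetone(), butanone()) is None
        assert match_exact(acetone(), propanal()) is None

    def test_benzene_kekulizations_pair_after_aromatization(self):
        from molharm.aromatics import aromatize
        mgr = extract_from_kcf([parse_kcf(benzene_kcf())])
        a = aromatize(benzene("a", 0), mgr)
        b = aromatize(benzene("b", 1), mgr)
        assert match_exact(a, b) is not None


class TestMatchGeneric:
    def test_acetyl_r_absorbs_a_methyl_of_acetone(self):
        edge = match_generic(acetyl_r("a"), acetone("b"))
        assert edge is not None and edge.relationship == "generic"
        absorbed = [atoms for atoms in edge.r_assignments.values() if atoms]
        assert len(absorbed) == 1 and len(absorbed[0]) == 1

    def test_acetyl_r_absorbs_the_ethyl_of_butanone(self):
        edge = match_generic(acetyl_r("a"), butanone("b"))
        assert edge is not None
        (r_atoms,) = [atoms for atoms in edge.r_assignments.values() if atoms]
        assert len(r_atoms) == 2

    def test_no_carbonyl_no_match(self):
        ethane = simple_compound("eth", ["C", "C"], [(0, 1, 1)])
        assert match_generic(acetyl_r("a"), ethane) is None

    def test_branch_at_wrong_attachment_point_fails(self):
        # propanal's extra carbon hangs off the methyl image, which is not
        # adjacent to the R group in the acetyl pattern
        assert match_generic(acetyl_r("a"), propanal("p")) is None

    def test_requires_r_atom_on_pattern_side(self):
        assert match_generic(acetone("a"), butanone("b")) is None


class TestMapRGroups:
    def test_r_may_absorb_an_empty_branch(self):
        # R-C matched onto lone C: nothing left over, R maps to hydrogen
        pattern = simple_compound("p", ["R", "C"], [(0, 1, 1)])
        target = simple_compound("t", ["C"], [])
        assign = map_R_groups(pattern, target, {1: 0})
        assert assign == {0: ()}

    def test_two_branches_two_r_groups(self):
        # R-C-C-R pattern onto C-C-C-C: each terminal carbon absorbed by its R
        pattern = simple_compound("p", ["R", "C", "C", "R"],
                                  [(0, 1, 1), (1, 2, 1), (2, 3, 1)])
        target = simple_compound("t", ["C", "C", "C", "C"],
                                 [(0, 1, 1), (1, 2, 1), (2, 3, 1)])
        assign = map_R_groups(pattern, target, {1: 1, 2: 2})
        assert assign == {0: (0,), 3: (3,)}

    def test_floating_component_fails(self):
        pattern = simple_compound("p", ["R", "C"], [(0, 1, 1)])
        target = simple_compound("t", ["C", "C"], [])  # second C unattached
        assert map_R_groups(pattern, target, {1: 0}) is None


class TestHarmonizeCompoundDatabases:
    def test_toy_scenario_exact_and_generic_edges(self, toy_scenario):
        dbA, dbB, _refs, expected_edges, _audit = toy_scenario
        mgr = extract_from_kcf([parse_kcf(benzene_kcf())])
        edges = harmonize_compound_databases(dbA, dbB, mgr)
        assert {(e.left_id, e.right_id, e.relationship) for e in edges} == expected_edges

    def test_generic_witnesses_revalidate(self, toy_scenario):
        dbA, dbB, *_ = toy_scenario
        edges = harmonize_compound_databases(dbA, dbB, None)
        for e in edges:
            if e.relationship != "generic":
                continue
            a, b = dbA[e.left_id], dbB[e.right_id]
            assert verify_mapping(a, b, e.mapping)
            assign = map_R_groups(a, b, e.mapping)
            assert assign is not None
            absorbed = {x for atoms in assign.values() for x in atoms}
            assert absorbed == set(range(b.n_atoms)) - set(e.mapping.values())

    def test_self_harmonization_gives_self_edges(self):
        db = {"x": acetone("x"), "y": butanone("y")}
        edges = harmonize_compound_databases(db, db, None)
        pairs = {(e.left_id, e.right_id) for e in edges}
        assert {("x", "x"), ("y", "y")} <= pairs

    def test_disjoint_formulas_no_edges(self):
        dbA = {"x": acetone("x")}
        dbB = {"y": simple_compound("y", ["N", "N"], [(0, 1, 3)])}
        assert harmonize_compound_databases(dbA, dbB, None) == []

    def test_symmetric_up_to_side_swap(self, toy_scenario):
        dbA, dbB, *_ = toy_scenario
        fwd = {(e.left_id, e.right_id, e.relationship)
               for e in harmonize_compound_databases(dbA, dbB, None)}
        rev = {(e.right_id, e.left_id, e.relationship)
               for e in harmonize_compound_databases(dbB, dbA, None)}
        assert fwd == rev


class TestHarmonizeReactionDatabases:
    def edges(self):
        # exact edges x<->x', y<->y', z<->z' expressed through toy acetone copies
        return harmonize_compound_databases(
            {k: acetone(k) if k == "x" else butanone(k) if k == "y" else propanal(k)
             for k in ("x", "y", "z")},
            {k: acetone(k) if k == "xp" else butanone(k) if k == "yp" else propanal(k)
             for k in ("xp", "yp", "zp")},
            None)

    def test_direct_bijection(self):
        redges = harmonize_reaction_databases(
            [Reaction("rA", [("x", 1), ("y", 1)], [("z", 1)])],
            [Reaction("rB", [("xp", 1), ("yp", 1)], [("zp", 1)])],
            self.edges())
        assert len(redges) == 1 and not redges[0].swapped_sides

    def test_side_swap_detected(self):
        redges = harmonize_reaction_databases(
            [Reaction("rA", [("x", 1), ("y", 1)], [("z", 1)])],
            [Reaction("rB", [("zp", 1)], [("xp", 1), ("yp", 1)])],
            self.edges())
        assert len(redges) == 1 and redges[0].swapped_sides

    def test_missing_participant_blocks_pairing(self):
        redges = harmonize_reaction_databases(
            [Reaction("rA", [("x", 1), ("y", 1)], [("z", 1)])],
            [Reaction("rB", [("xp", 1)], [("zp", 1)])],
            self.edges())
        assert redges == []

    def test_stoichiometry_must_match_unless_relaxed(self):
        left = [Reaction("rA", [("x", 2)], [("z", 1)])]
        right = [Reaction("rB", [("xp", 1)], [("zp", 1)])]
        assert harmonize_reaction_databases(left, right, self.edges()) == []
        assert len(harmonize_reaction_databases(left, right, self.edges(),
                                                require_stoich=False)) == 1

    def test_ec_top_level_must_agree_when_present(self):
        left = [Reaction("rA", [("x", 1)], [("z", 1)], ec_numbers=["1.1.1.1"])]
        right = [Reaction("rB", [("xp", 1)], [("zp", 1)], ec_numbers=["2.3.1.5"])]
        assert harmonize_reaction_databases(left, right, self.edges()) == []
        assert len(harmonize_reaction_databases(left, right, self.edges(),
                                                check_ec=False)) == 1


class TestReferenceAudit:
    def test_toy_scenario_one_pair_per_category(self, toy_scenario):
        dbA, dbB, ref_pairs, _edges, expected_audit = toy_scenario
        edges = harmonize_compound_databases(dbA, dbB, None)
        audits, summary = categorize_reference_pairs(ref_pairs, dbA, dbB, edges)
        assert {(a.remote_id, a.local_id): a.category for a in audits} == expected_audit
        assert summary["missed_total"] == 3 and summary["validated"] == 1

    def test_categories_partition_the_input(self, toy_scenario):
        dbA, dbB, ref_pairs, _edges, _audit = toy_scenario
        edges = harmonize_compound_databases(dbA, dbB, None)
        audits, summary = categorize_reference_pairs(ref_pairs, dbA, dbB, edges)
        assert summary["n_pairs"] == len(ref_pairs) == len(audits)
        assert (summary["validated"] + summary["missed_total"]) == summary["n_pairs"]

    def test_summary_percentages_use_missed_total_denominator(self):
        s = audit_summary(1, 1, 2)
        assert s["missed_total"] == 4
        assert s["invalid_reference_pct"] == 25.0
        assert s["other_pct"] == 50.0
        assert audit_summary(0, 0, 0)["invalid_reference_pct"] == 0.0
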
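"""Mapping matrix, backtracking search, prunings — vs exhaustive oracles."""

import numpy as np
import pytest

from molharm.fixtures import (
    FixtureSpec,
    acetone,
    butanone,
    cyclopropane,
    embed_substructure,
    propane,
    random_compound,
    random_pattern_target_pair,
    simple_compound,
)
from molharm.graph_metrics import all_pairs_shortest_distance
from molharm.substructure import (
    MatchOptions,
    brute_force_mappings,
    build_mapping_matrix,
    find_mappings,
    is_substructure,
    verify_mapping,
)
from tests.conftest import mapping_set, nx_monomorphisms


def study_pairs(n_pairs: int):
    """Seeded (pattern, target) pairs within the brute-force size guard."""
    for s in range(n_pairs):
        n_pat = 5 + s % 4
        n_extra = min(3 + s % 5, 12 - n_pat)
        yield random_pattern_target_pair(seed=s, planted=(s % 2 == 0),
                                         n_pattern=n_pat, n_extra=n_extra)


class TestMappingMatrix:
    def test_oxygen_row_has_single_candidate(self):
        m = build_mapping_matrix(acetone(), acetone(), MatchOptions())
        assert m.M[3].sum() == 1 and m.M[3][3]

    def test_carbonyl_carbon_needs_double_bond_capacity(self):
        # methyl carbons cannot host the carbonyl carbon: no double bond to dominate
        m = build_mapping_matrix(acetone(), acetone(), MatchOptions())
        assert m.M[1].sum() == 1 and m.M[1][1]

    def test_ring_atoms_never_map_into_trees(self):
        m = build_mapping_matrix(cyclopropane(), propane(), MatchOptions())
        assert m.infeasible()
        assert not m.M.any()

    def test_color_check_requires_inputs(self):
        with pytest.raises(ValueError):
            build_mapping_matrix(acetone(), acetone(),
                                 MatchOptions(color_level_check=True))


class TestBacktrackMappings:
    @pytest.mark.parametrize("pattern,target,count", [
        (simple_compound("c", ["C"], []), acetone(), 3),
        (acetone(), acetone(), 2),      # methyl-swap automorphism
        (acetone(), butanone(), 2),     # both carbons adjacent to the carbonyl
        (simple_compound("cc", ["C", "C"], [(0, 1, 1)]),
         simple_compound("cc2", ["C", "C"], [(0, 1, 1)]), 2),
    ])
    def test_known_embedding_counts(self, pattern, target, count):
        res = find_mappings(pattern, target)
        assert len(res.mappings) == count
        assert mapping_set(res.mappings) == mapping_set(
            brute_force_mappings(pattern, target))

    def test_results_sorted_lexicographically(self):
        res = find_mappings(acetone(), butanone())
        keys = [[m[i] for i in sorted(m)] for m in res.mappings]
        assert keys == sorted(keys)

    def test_candidates_scanned_in_ascending_target_order(self):
        res = find_mappings(simple_compound("c", ["C"], []), acetone(),
                            stop_after_first=True)
        assert res.mappings[0] == {0: 0}

    def test_node_budget_aborts(self):
        a = random_compound(FixtureSpec(seed=3, n_atoms=6))
        b, _ = embed_substructure(a, 4, seed=4)
        res = find_mappings(a, b, MatchOptions(max_nodes=2))
        assert res.aborted


class TestOracleEquivalence:
    def test_matches_brute_force_on_200_random_pairs(self):
        # prunings must never change the mapping set, only the search cost
        for a, b in study_pairs(200):
            expected = mapping_set(brute_force_mappings(a, b))
            assert mapping_set(find_mappings(a, b, MatchOptions()).mappings) == expected
            assert mapping_set(find_mappings(a, b, MatchOptions.baseline()).mappings) == expected

    def test_matches_networkx_vf2_on_named_and_random_pairs(self):
        pairs = [(acetone(), butanone()), (cyclopropane(), propane())]
        pairs += [p for _, p in zip(range(20), study_pairs(20))]
        for a, b in pairs:
            assert mapping_set(find_mappings(a, b).mappings) == nx_monomorphisms(a, b)

    def test_matches_rdkit_substructure_matches_on_named_pairs(self):
        from rdkit import Chem

        from molharm.compound import write_molfile
        pairs = [(acetone(), butanone()), (acetone(), acetone()),
                 (cyclopropane(), propane())]
        for a, b in pairs:
            pat = Chem.MolFromMolBlock(write_molfile(a), sanitize=False)
            tgt = Chem.MolFromMolBlock(write_molfile(b), sanitize=False)
            rdkit_maps = {tuple(sorted(enumerate(match)))
                          for match in tgt.GetSubstructMatches(pat, uniquify=False)}
            assert mapping_set(find_mappings(a, b).mappings) == rdkit_maps


class TestPruningEffectiveness:
    def test_prunings_never_increase_expanded_nodes(self):
        strict_reduction_seen = False
        for a, b in study_pairs(200):
            full = find_mappings(a, b, MatchOptions())
            base = find_mappings(a, b, MatchOptions.baseline())
            assert full.expanded_nodes <= base.expanded_nodes
            if full.expanded_nodes < base.expanded_nodes:
                strict_reduction_seen = True
        assert strict_reduction_seen


class TestPlantedSubstructures:
    def test_planted_embedding_is_recalled(self):
        for seed in range(100):
            a = random_compound(FixtureSpec(seed=seed, n_atoms=4 + seed % 5))
            b, planted = embed_substructure(a, extra_atoms=3 + seed % 4, seed=seed + 5000)
            ok, _first = is_substructure(a, b)
            assert ok
            res = find_mappings(a, b)
            assert tuple(sorted(planted.items())) in mapping_set(res.mappings)

    def test_planted_mapping_satisfies_distance_rule(self):
        for seed in range(30):
            a = random_compound(FixtureSpec(seed=seed, n_atoms=6))
            b, planted = embed_substructure(a, extra_atoms=4, seed=seed + 7000)
            Da = all_pairs_shortest_distance(a)
            Db = all_pairs_shortest_distance(b)
            for i in planted:
                for k in planted:
                    if Da[i][k] < a.n_atoms:
                        assert Da[i][k] >= Db[planted[i]][planted[k]]


class TestIsSubstructure:
    def test_direction_matters(self):
        assert is_substructure(acetone(), butanone())[0]
        assert not is_substructure(butanone(), acetone())[0]

    def test_every_compound_contains_itself(self):
        for seed in range(10):
            c = random_compound(FixtureSpec(seed=seed, n_atoms=7))
            ok, witness = is_substructure(c, c)
            assert ok and verify_mapping(c, c, witness)

    def test_transitive_composition_is_valid(self):
        # a witness a->b composed with b->c is a valid a->c mapping
        for seed in range(20):
            a = random_compound(FixtureSpec(seed=seed, n_atoms=5))
            b, m_ab = embed_substructure(a, 3, seed=seed + 1)
            c, m_bc = embed_substructure(b, 3, seed=seed + 2)
            composed = {i: m_bc[j] for i, j in m_ab.items()}
            assert verify_mapping(a, c, composed)


class TestAromaticTolerantMode:
    def test_kekulization_variants_interchange_in_rings(self):
        hex1 = simple_compound("k1", ["C"] * 6,
                               [(i, (i + 1) % 6, 1 + i % 2) for i in range(6)])
        hex2 = simple_compound("k2", ["C"] * 6,
                               [(i, (i + 1) % 6, 4) for i in range(6)])
        opts = MatchOptions.for_aromatic()
        assert find_mappings(hex1, hex2, opts).mappings == []  # order 1 never pools
        hex3 = simple_compound("k3", ["C"] * 6,
                               [(i, (i + 1) % 6, 2 if i % 2 else 4) for i in range(6)])
        assert len(find_mappings(hex3, hex2, opts).mappings) > 0

    def test_pooling_restricted_to_ring_bonds(self):
        chain_double = simple_compound("d", ["C", "C"], [(0, 1, 2)])
        chain_aromatic = simple_compound("a", ["C", "C"], [(0, 1, 4)])
        opts = MatchOptions.for_aromatic()
        assert find_mappings(chain_double, chain_aromatic, opts).mappings == []
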
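"""Shared helpers: graph conversions and independent oracles for the suite."""

import networkx as nx
import pytest

from molharm.compound import Compound


def to_networkx(c: Compound) -> nx.Graph:
    g = nx.Graph()
    for a in c.atoms:
        g.add_node(a.index, element=a.element, is_R=a.is_R)
    for b in c.bonds:
        g.add_edge(b.first_atom, b.second_atom, order=b.order)
    return g


def mapping_set(mappings) -> set:
    """Canonical comparable form of a list of atom mappings."""
    return {tuple(sorted(m.items())) for m in mappings}


def nx_monomorphisms(pattern: Compound, target: Compound) -> set:
    """Independent non-induced subgraph monomorphism oracle (networkx VF2)."""
    gm = nx.algorithms.isomorphism.GraphMatcher(
        to_networkx(target), to_networkx(pattern),
        node_match=lambda x, y: x["element"] == y["element"] and x["is_R"] == y["is_R"],
        edge_match=lambda x, y: x["order"] == y["order"])
    out = set()
    for m in gm.subgraph_monomorphisms_iter():
        out.add(tuple(sorted((v, k) for k, v in m.items())))
    return out


@pytest.fixture
def toy_scenario():
    from molharm.fixtures import toy_harmonization_scenario
    return toy_harmonization_scenario()
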
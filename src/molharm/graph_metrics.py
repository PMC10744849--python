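"""Shortest-distance machinery: all-pairs hop counts and distance to R groups.

Distances count bonds (unit edge weights; bond order is irrelevant).  The
"unreached" sentinel is the atom count ``n`` — strictly larger than any real
path length (at most n-1) — so downstream pruning can compare plain
integers.  Distances to R groups come from a multi-source Dijkstra seeded
with every R atom at distance 0.
"""

from __future__ import annotations

import heapq

import numpy as np

from molharm.compound import Compound


def all_pairs_shortest_distance(c: Compound) -> np.ndarray:
    """Floyd–Warshall hop-count distances; unreachable pairs hold the sentinel n."""
    n = c.n_atoms
    D = np.full((n, n), n, dtype=np.int64)
    np.fill_diagonal(D, 0)
    for b in c.bonds:
        D[b.first_atom, b.second_atom] = 1
        D[b.second_atom, b.first_atom] = 1
    for k in range(n):
        D = np.minimum(D, D[:, k, None] + D[None, k, :])
    # re-clip: sums of sentinels overflow the convention, never the integers
    np.minimum(D, n, out=D)
    return D


def distance_to_R(c: Compound) -> np.ndarray:
    """Shortest distance from every atom to the nearest R-group atom.

    Multi-source Dijkstra: the priority queue starts with all R atoms at
    distance 0; popping an atom finalizes its distance, and a neighbor is
    pushed whenever the tentative distance improves.  Ties in the queue are
    broken by atom index for a deterministic traversal (the distances are
    tie-independent anyway).  A compound without R atoms gets all sentinels.
    """
    n = c.n_atoms
    DR = np.full(n, n, dtype=np.int64)
    heap = [(0, a.index) for a in c.atoms if a.is_R]
    heapq.heapify(heap)
    for _, i in heap:
        DR[i] = 0
    adj = [c.neighbors(i) for i in range(n)]
    done = [False] * n
    while heap:
        d, i = heapq.heappop(heap)
        if done[i] or d > DR[i]:
            continue
        done[i] = True
        for j, _order in adj[i]:
            if DR[j] > d + 1:
                DR[j] = d + 1
                heapq.heappush(heap, (d + 1, j))
    return DR
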
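# molharm

Atom-level harmonization of compounds and reactions across metabolic
database snapshots.

Public metabolic resources (KEGG, MetaCyc, HMDB, ...) describe overlapping
chemistry under incompatible nomenclatures, which blocks the construction of
integrated, atom-resolved metabolic networks. `molharm` pairs compound and
reaction records across two database snapshots directly from chemical
structure: no names, no registry numbers, no InChI — which cannot express
the R-group ("Markush") generic compounds these databases are full of.

## What is inside

A compound is an undirected labeled graph over its *n* non-hydrogen atoms
with bond orders in {1 single, 2 double, 3 triple, 4 aromatic}, held in an
adjacency matrix *N* (n × n, symmetric, zero diagonal).

- **Canonical identifiers** — neighborhood-specific layered coloring
  (1-dimensional Weisfeiler–Lehman refinement): the layer-0 color of an atom
  is its element; the layer-k color combines its layer-(k−1) color with the
  sorted multiset of (bond order, neighbor color) pairs. The sorted
  final-layer colors, prefixed by the heavy-atom formula, identify the
  compound independent of atom numbering.
- **Substructure search** — a mapping matrix *M* (n × m) of per-atom-pair
  candidacy (same element; ring atoms map to ring atoms; per-bond-order and
  per-neighbor-element counts of the pattern atom dominated by the target
  atom's) followed by backtracking enumeration of all injective mappings
  `O2OM` with a "used atom" array `U`. Partial mappings are additionally
  pruned with the shortest-distance rule
  `D_A[i][k] ≥ D_B[O2OM[i]][O2OM[k]]` — valid because adding atoms or bonds
  never lengthens a shortest path. All criteria are necessary conditions,
  so pruning shrinks the search tree without changing the answer.
- **Distances** — Floyd–Warshall all-pairs hop counts `D`, and a
  multi-source Dijkstra giving each atom's distance `d_R` to the nearest
  R-group atom.
- **Generic matching** — a compound with R groups pairs with a specific
  partner when its non-R scaffold embeds in the partner (atoms compared by
  their colors at level `d_R − 1`, which are blind to everything at or
  beyond the R boundary) and every unmatched branch of the partner attaches
  at an R-adjacent position.
- **Aromatic curation** — an `AromaticManager` harvests ring systems from
  KCF-typed aromatic atoms, finds them in arbitrary compounds with a
  kekulization-tolerant search, and rewrites matched ring bonds to order 4
  so alternative kekulizations share one identifier.
- **Harmonization & audit** — exact edges (equal identifiers), generic
  edges (substructure + R coverage), reaction edges (participant multiset
  bijection through compound edges, sides may swap), and categorization of
  asserted cross-references as validated / invalid reference / inconsistent
  formula / other.

## Worked example

```sh
python examples/harmonize_toy_databases.py
```

```
harmonized edges (4):
  A_acetone <-> B_acetone  [exact]
  A_acetylR <-> B_acetone  [generic]  (R groups absorb 1 atom(s))
  A_acetylR <-> B_butanone  [generic]  (R groups absorb 2 atom(s))
  A_benzene <-> B_benzene  [exact]

cross-reference audit:
  B_acetone -> A_acetone: validated
  B_broken -> A_benzene: invalid_reference
  B_butanone -> A_acetone: inconsistent_formula
  B_propanal -> A_acetone: other

missed total 3: invalid 33.33%, inconsistent formulas 33.33%, other 33.33%
```

The two exact edges pair structurally identical records (benzene matches
across different kekulizations thanks to aromatic curation). The generic
acetyl compound R–CO–CH₃ pairs with acetone (its R absorbs one methyl
carbon) and with 2-butanone (the R absorbs the two-carbon ethyl branch).
The audit triages each asserted cross-reference: one confirmed by
harmonization, one pointing at a record with no parsable structure, one
whose formulas cannot agree (C4O vs C3O), and one structural mismatch at
equal formula (propanal vs acetone).

The same pipeline is available from the shell:

```sh
molharm aromatize  kcf_dir/ manager.json
molharm harmonize compound dbA/ dbB/ edges.json --manager manager.json
molharm audit      refs.tsv dbA/ dbB/ edges.json audit.tsv
```

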
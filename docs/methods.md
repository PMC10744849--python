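# Methods

## Compound model

A compound is an undirected labeled graph over its non-hydrogen atoms.
Hydrogens are removed at parse time (with their bonds), so every algorithm
operates on heavy atoms only; atom order is file order after removal.
Bonds carry the ctfile integer order (1 single, 2 double, 3 triple,
4 aromatic); at most one bond may join an atom pair and self-bonds are
rejected at construction. Multiple disconnected components are allowed in
one compound (salts); identifiers and searches treat the whole graph.

R-group placeholders are recognized from the marker set {R, R#, *, X} plus
any KCF atom type beginning with "R"; the set is configurable because
databases disagree on the convention. Charges are parsed from `M  CHG`
property lines and stored, but excluded from matching and from the base
colors by default (an `include_charge` switch exists on the coloring
functions); the input formats are not explicit enough about charge
conventions across databases to make them a safe default discriminator.

Formulas are heavy-atom formulas in Hill order with the R count appended
(`C2OR1`), with no implicit-hydrogen valence model. This is deliberately
weaker than a full molecular formula but sufficient to flag cross-reference
pairs whose structures cannot possibly agree, which is its only use here.

Ring perception flags an atom as cyclic iff it is incident to a non-bridge
edge; bridges come from one iterative depth-first pass (low-link values).
The set of non-bridge ("ring") bonds is cached per compound and reused by
the aromatic-tolerant search.

Supported dialects: MDL molfile V2000 (V3000 is rejected loudly) and
KEGG-style KCF (ENTRY/ATOM/BOND blocks, 1-based indices converted to
0-based). The writer emits V2000 that round-trips through the parser;
the fixed-width format caps compounds at 999 atoms.

## Layered coloring and identifiers

Colors refine layer by layer: layer 0 is the element symbol alone (R atoms
collapse to "R"); the layer-k color is the layer-(k−1) color plus the
lexicographically sorted multiset of `(bond order, neighbor layer-(k−1)
color)` pairs, serialized with balanced delimiters. No hashing is used —
colors are complete strings — so equality is exact, reproducible across
platforms, and meaningful *between* compounds, which the generic-matching
criterion requires. The cost is string growth with layer depth; for
database-sized molecules (refinement stabilizes in a handful of layers,
never more than the atom count) this is cheap, and it removes any
possibility of silent collision.

With automatic depth, refinement stops one layer after the induced
partition stabilizes. The compound identifier is the heavy-atom formula
plus the sorted final-layer colors. Layer-0 colors intentionally carry no
degree or bond information: this makes an atom's layer-k color a function
of its radius-k ball only, which is exactly what the generic-compound
criterion needs (see below).

Known limitation: 1-WL refinement cannot separate certain highly regular
non-isomorphic graphs. Exact matching therefore also compares the
bond-order multiset as a safety net, and recovers an explicit atom mapping
by substructure search rather than trusting color equality alone.

## Distances

All-pairs distances are Floyd–Warshall hop counts (bond order ignored —
distances count bonds). The "unreached" sentinel is the atom count n,
strictly larger than any real path length, so pruning comparisons stay
plain integer comparisons. Distance-to-R is a multi-source Dijkstra seeded
with every R atom at distance zero; queue ties break by atom index for a
deterministic traversal (results are tie-independent). A compound without
R atoms gets all-sentinel distances, which downstream logic reads as
"criterion inapplicable".

One subtlety: in the distance-pruning rule the pattern-side sentinel must
not be compared against genuine target-side distances (the target may be
larger than the pattern, so its real distances can exceed the pattern's
sentinel). The rule therefore skips pairs disconnected in the pattern —
no constraint exists for them — while a target-side sentinel against a
finite pattern distance prunes, since a valid embedding forces the images
of connected atoms to stay connected.

## Substructure search

Candidacy (the mapping matrix) requires, per enabled criterion: equal
element and R status; pattern ring atoms map only to target ring atoms
(one-directional, because extending a structure can create rings through
previously acyclic atoms but never destroy the pattern's); the pattern
atom's per-bond-order counts dominated by the target atom's; likewise its
per-neighbor-element counts; and, in generic mode, equal colors at level
`d_R − 1` for pattern atoms with finite positive distance `d_R` to the
nearest R group. That color level depends only on atoms strictly closer
than the R boundary, so a generic compound and its specific counterpart
must agree there. R atoms of the pattern carry no row constraint: matching
operates on the non-R scaffold and R satisfaction is validated afterwards.

The backtracking enumeration visits pattern atoms in ascending index order
and scans candidates in ascending target index, backtracking to the
previous atom's next candidate on exhaustion; it records every complete
injective mapping (search continues after each hit) in lexicographic
order. Each tentative assignment is validated against previously assigned
bonded neighbors (bond orders must be compatible) and, when enabled,
against the shortest-distance rule for *all* previously assigned atoms.

Visit order is a genuinely open design point. A rarest-candidate-first
(fail-first) order is available as an option, but the default is plain
index order: with a fixed order the search tree under stronger criteria is
a strict subtree of the weaker run's tree, so "pruning never increases the
number of expanded nodes" holds by construction on every instance, not
merely on average. `expanded_nodes` counts candidate assignments examined
and is the hardware-independent measure of search effort used throughout.

Aromatic-tolerant mode pools bond orders {2, 4} on ring bonds, both in the
dominance counts and in bond-compatibility checks, so a kekulized double
bond matches a curated aromatic bond. Order-1 ring bonds never pool: a
single bond is not evidence of delocalization, which is also what rejects
cyclohexane against a benzene fragment.

A node-budget cap (default 10^6 expansions per fragment search) turns
pathological fused-ring cases into a warning plus a partial result instead
of a hang.

The exhaustive oracle (`brute_force_mappings`) enumerates injective maps
filtered only by element equality and bond compatibility, guarded to
pattern ≤ 8 / target ≤ 12 atoms. It shares no pruning logic with the
optimized search and is the ground truth in the test suite, alongside
networkx's VF2 monomorphism matcher and RDKit substructure matching as
third-party cross-checks.

## Aromatic library

Fragments are the connected components of KCF-typed aromatic atoms
(default types: C8x, C8y, N4x, N4y, N5x, N5y — KEGG's aromatic carbon and
nitrogen families; the list is configuration, not code). Components whose
atoms are not all cyclic are discarded as annotation noise. Fragments are
stored with bond orders as extracted (kekulized if the source was) and
deduplicated across the corpus by canonical identifier; detection runs
largest-fragment-first and merges overlapping matches, so fused systems
prefer one large match over several small ones. Applying a detection
rewrites every bond internal to a matched set to order 4 — idempotent, and
touching nothing but bond orders.

## Harmonization

Exact edges require equal identifiers (plus the bond-multiset safety net)
after aromatization; the atom mapping is recovered by a full search.
Generic edges require the generic side's scaffold to embed under the
color-level criterion and every unmatched target branch to be absorbed: a
branch may attach to the mapped image only at atoms whose preimage is
adjacent to an R, each branch goes to the smallest-index eligible R
(branches attaching at several eligible sites included), and a floating
component that attaches nowhere fails — an R stands for a bonded
substituent, not a detached species. R atoms left without a branch absorb
an empty one (R may stand for hydrogen).

Candidate generation buckets by formula: exact candidates share the full
heavy-atom formula; generic candidates must dominate the generic side's
non-R element counts. When both sides carry R groups both directions are
attempted. Output is sorted by id pair and serialized with stable key
order, so runs are byte-identical regardless of worker count.

Reaction edges require a bijection between participant multisets — sides
may swap wholesale — with every pair backed by a compound edge or an
identical id; stoichiometric coefficients must match exactly by default
(flag to relax), and EC numbers, when present on both sides, must share a
top-level class (soft filter, skippable). The bijection search is exact
backtracking; participant lists are small.

Reference auditing applies a fixed decision order per (remote id, local
id) pair: remote record missing or structureless → invalid reference;
pair present among harmonized edges → validated; formulas differ →
inconsistent formula; otherwise → other. Categories are therefore mutually
exclusive, and summary percentages are taken over the missed total
(validated pairs excluded), rounded half-up to two decimals.

## Synthetic study conditions

The fixture generators define the conditions every oracle suite runs
under. `random_compound` grows a connected spanning tree and closes rings
with probability 0.15 by default, under per-element valence caps (C 4,
N 3, O 2, halogens 1) with a palette biased 3:1:1 toward carbon over
nitrogen and oxygen — small, drug-fragment-like graphs where element
repetition makes matching nontrivial. `embed_substructure` plants a
compound verbatim inside a larger one by attaching extra atoms at
spare-valence positions, so the identity mapping is a known witness.
The oracle-equivalence study uses 200 seeded pairs with patterns of 5–8
atoms and targets up to 12 — the exhaustive oracle's tractability bound —
half of them planted (guaranteeing non-empty mapping sets), half
independent (mostly empty). Recall studies use 100 planted pairs;
distance and invariance studies use 100 random graphs and 500
permutations. These sizes keep every suite and the acceptance script in
the seconds range while exercising all code paths.

What the generators do not emulate: realistic chemistry (functional-group
statistics, aromatic prevalence, charge states), stereochemistry, and
database-scale compound sizes. Passing tests therefore demonstrate
algorithmic correctness — search completeness, pruning soundness,
identifier invariance, end-to-end bookkeeping — not retrieval quality on
real database dumps.

The toy harmonization scenario fixes two snapshots by hand: acetone,
benzene and a generic acetyl compound on one side; acetone, 2-butanone, an
alternately kekulized benzene, a structureless record and propanal on the
other. Ground truth (2 exact edges, 2 generic edges, one audit pair per
category) was constructed so that every audit category and both edge kinds
are exercised by exactly one case, and is independently confirmed by the
brute-force oracle in the tests.

## Numerical and determinism choices

Everything is integer arithmetic except audit percentages (rounded
half-up, two decimals, with a tiny epsilon against binary representation
of exact halves). All randomness flows through explicitly seeded
generators; no global random state is touched. Mapping lists, edge lists,
JSON keys and TSV rows are sorted, so repeated runs — and runs with
different worker counts — produce byte-identical files. The published
missed-pair tables that the audit arithmetic is checked against round
their columns to sum to exactly 100.00, which no single consistent
rounding rule reproduces digit-for-digit; the package reports consistent
half-up rounding, agreeing with every published figure to within one unit
in the last printed digit.

## Known limitations

- 1-WL identifier collisions on regular graphs (mitigated, not eliminated,
  by the formula prefix and bond-multiset check).
- No stereochemistry, isotopes, or implicit-hydrogen modeling; tautomers
  and resonance forms beyond ring aromatization do not unify.
- Aromaticity is library-driven (fragments harvested from typed inputs),
  not perceived from first principles; rings absent from the library stay
  kekulized.
- Circular–linear interconvertible forms are not paired: doing so reliably
  requires reaction evidence from both databases, and a hook for such a
  matcher is left open rather than guessed at.
- Generic-generic pairing tries both orientations but does not rank
  alternative witnesses chemically; the lexicographically first witness is
  reported.
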
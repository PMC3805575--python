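# Methods

## Model and search semantics

The package answers subgraph queries over a database *D* of simple
undirected graphs with one string label per vertex. Matching semantics are
**non-induced subgraph monomorphism**: an occurrence of a connected query
*Q* in *G* is an injective, label-preserving map of *V(Q)* into *V(G)*
under which every query edge is a data edge; data edges outside the image
are ignored. Labels compare by exact string equality — there is no label
hierarchy or wildcard. All distinct mappings are reported, so a query with
*k* automorphisms contributes its embeddings *k* times; this is the
convention that makes occurrence counts composable and is what the
brute-force oracle counts too. Queries must be connected (the component
decomposition below assumes it); database graphs may be disconnected and
are indexed normally.

## Features and the path trie

A *feature* is the label sequence of a **vertex-simple** path of at most
*lp* edges (a path with *k* edges has *k+1* labels). Vertex-simplicity
keeps per-graph feature counts finite and makes the brute-force path
counter used in tests well-defined; edge-simple or walk-based variants
would count differently but filter the same graphs no less soundly. Every
prefix of an enumerated path is a feature in its own right, so one trie
answers every feature length up to *lp*.

Each trie node stores `graph_id -> {start_vertex -> count}`: how many
simple paths realize the node's label sequence from each start vertex.
Storing *per-start counts* rather than a bare start set is deliberate —
the vertex-level filter must reject a data vertex that starts a feature
only once when the query vertex starts it twice, which a start set cannot
express. Start sets shrink down the trie (a path realizing a feature
realizes every prefix from the same start) but counts need not: one short
path can extend to many longer ones, so no count monotonicity is assumed
anywhere.

`lp` is measured in edges, defaults to 4, and is accepted in 1..10.
Larger `lp` filters more sharply but the trie grows roughly with the
number of simple paths, which explodes on dense graphs; 4 is a practical
balance for the sparse biological networks this workload resembles.
Raising `lp` can only shrink candidate sets (features are a superset), and
the final occurrence set is invariant in `lp` — both properties are
asserted by tests.

## Filtering

Two stages with distinct comparison rules:

- **Graph level** — total counts. *G* survives iff for every query
  feature *f*, total_count_G(f) ≥ total_count_Q(f). Implemented as a
  lockstep walk of the query trie inside the database trie, pruning the
  survivor set feature by feature.
- **Vertex level** — per-start counts. Data vertex *v* is matchable for
  query vertex *u* iff every feature starting at *u* with multiplicity *c*
  starts at *v* with multiplicity ≥ *c*. The length-1 feature forces label
  equality.

The union of matchable vertices induces a subgraph of each candidate;
its maximal connected components are computed, and a component is kept
only if it has at least |V(Q)| vertices and a non-empty restriction of
every query vertex's matchable set. The size cutoff is a pure optimization
— no occurrence fits in a smaller component — and the soundness test
verifies it drops nothing. The vertex filter is a single pass (no
fixed-point iteration of mutual pruning), and extracted components are not
re-indexed; both choices trade a little filtering power for simplicity and
cannot affect correctness, only the work left to the matcher.

## Matching

A VF2-style backtracking search runs per seed task. The query vertex with
the largest restricted candidate list in a component is the *root* (ties:
smallest id); each data vertex in the root's list seeds one task, so tasks
partition the occurrence set exactly (every occurrence maps the root
somewhere unique) and can run in any order or in parallel. Longer lists
are scheduled first since they parallelize best.

Within a task, the next query vertex to map is the unmapped neighbor of
the mapped set with the smallest restricted list (ties: smallest id), and
data candidates are tried in ascending id — any order is correct; this one
is deterministic. Feasibility rules: injectivity, restricted-set
membership (which subsumes label equality), edge consistency with every
already-mapped neighbor, and a one-sided lookahead — the number of
unmapped query neighbors of *u* must not exceed the unused data neighbors
of *v*. The lookahead is one-sided because the semantics are monomorphism:
surplus data neighbors are legal. A count-only mode skips materializing
mappings.

## Determinism and parallelism

Index building parallelizes over (graph, same-label vertex list) units and
matching over seed tasks, both through a fork-based process pool with
dynamic dispatch. Trie merging is commutative and associative, and
occurrences are re-sorted by (graph id, mapping tuple) after the pool
returns, so serialized indexes and result files are byte-identical for any
worker count. `workers=1` bypasses the pool entirely.

## Persistence

Indexes persist as a single JSON document: a header (magic string, format
version, `lp`, graph count), a graph catalog (name, vertex count, edge
count per graph — used to detect a database/index mismatch at query time),
and a nested preorder dump of the trie. The logical schema is normative;
the byte layout is whatever the JSON serializer emits. Wrong magic, wrong
version, or truncation raise a load error.

## Synthetic data and the oracle

The generator emulates the shape of motif-search workloads, not any real
dataset's statistics: Erdős–Rényi-style graphs of 10–30 vertices with
average degree 2–4, label alphabets of 2–6 symbols, uniform or Zipf-skewed
(skew produces the long matchable lists where the root heuristic matters).
Queries are grown from a uniformly random edge of a host graph by
repeatedly attaching a uniformly random frontier edge until the requested
edge count (4, 8, or 16 in the default envelope), so every query is
connected, reflects the host's degree and label statistics, and occurs in
its host by construction. `plant_query` wires vertex-disjoint query copies
into a random host through single bridge edges; with a host alphabet
disjoint from the query's, filtering must return each copy as its own
component, which the tests assert. What passing these tests does **not**
show: behavior on real interaction networks or compound libraries, whose
degree distributions are heavy-tailed and label frequencies far more
skewed than the generator's, and any wall-clock performance claim.

`brute_force_search` is the reference: plain backtracking over a fixed
breadth-first query-vertex order with label-class candidates and no
filtering, sharing no code with the trie or the matcher. It is itself
guarded in tests against networkx's generic monomorphism matcher on small
instances.

## Numerical and degenerate-input choices

No floating point is involved anywhere; all quantities are exact counts.
Tie-breaks are always by smallest id. Degenerate inputs: an empty database
indexes to an empty trie; a single-vertex query degenerates to a label
histogram test; a database graph smaller than the query is filtered by the
component-size cutoff; duplicate edge lines in input files collapse
silently, while self-loops and out-of-range endpoints are parse errors
naming the offending line.

## Test problem sizes

The randomized suites use databases of 10–20 graphs drawn from the
envelope above: 200 seeded trials for pipeline-vs-oracle equality and
filter soundness, 50 for trie-count verification on graphs of ≤ 8
vertices, 20 each for worker-count determinism and planted-copy recovery.
These sizes keep the whole suite in the tens of seconds while exercising
every filter stage and matcher branch.

## Known limitations

- Dense or large-alphabet-path-rich graphs make the trie large; there is
  no feature hashing or low-support pruning.
- No edge labels, directed edges, or approximate matching.
- The per-component throttling heuristic for matcher instances is a global
  dynamic queue over all seed tasks rather than a per-component cap.
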
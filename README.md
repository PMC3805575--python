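# pathtrie

Exhaustive subgraph search over databases of vertex-labeled undirected
graphs, built for the motif-query workloads of systems biology and
cheminformatics: find **every** occurrence of a small connected query graph
(a feed-forward loop in an interaction network, a substructure in a
compound library) inside each graph of a database, quickly, by filtering
before matching.

## The method

A database is an ordered collection of simple undirected graphs
*G = (V, E, lab)* where *lab* assigns each vertex one label from an
alphabet Σ. An **occurrence** of a connected query *Q* in *G* is a
subgraph monomorphism: an injective map *f : V(Q) → V(G)* with
*lab(f(u)) = lab(u)* for every query vertex and *(f(u), f(v)) ∈ E(G)* for
every query edge — extra data edges are allowed.

Enumerating occurrences directly is exponential, so the search is
filter-and-verify:

1. **Building.** Every vertex-simple path of at most *lp* edges contributes
   its label sequence (a *feature*) to a prefix tree. Each trie node stores,
   per graph and per start vertex, how many paths realize that feature from
   that start. Features of one graph are collected per same-label vertex
   list; lists are independent work units for a process pool, and the
   partial tries merge into one global trie whose content is independent of
   worker count.
2. **Filtering.** The query is indexed the same way. A graph survives only
   if each query feature occurs at least as often as in the query (total
   counts); a data vertex *v* can host query vertex *u* only if every
   feature starting at *u* starts at *v* at least as many times (per-start
   counts). The subgraph induced by the surviving vertices is split into
   maximal connected components; components smaller than the query or
   missing some query vertex's candidates are dropped. The filter is sound:
   it never discards a graph, vertex, or component that carries an
   occurrence.
3. **Matching.** A VF2-style backtracking matcher enumerates all
   occurrences inside each component. Work is split into seed tasks — one
   matcher instance per candidate data vertex of the query vertex with the
   longest candidate list — which partition the occurrence set exactly and
   run on a process pool. Results merge in canonical (graph id, mapping)
   order, so output is byte-identical for any worker count.

## Worked example

`examples/01_index_and_search.py` indexes two small molecules and searches
a C–N–C probe:

```
database graphs : 2
candidates      : 2
components      : 2
occurrences     : 4
0	molecule-1	0	0->0;1->1;2->2
0	molecule-1	1	0->2;1->1;2->0
1	molecule-2	0	0->0;1->1;2->2
1	molecule-2	1	0->2;1->1;2->0
```

Each TSV line is one occurrence: graph id, graph name, a per-graph ordinal,
and the query-vertex→data-vertex mapping. The symmetric probe fits both
ways around each C–N–C path, hence two occurrences per graph.
`examples/02_filtering_decomposition.py` shows the filter carving a
21-vertex host down to two 3-vertex components, and
`examples/03_synthetic_oracle.py` verifies the pipeline against index-free
brute force on a random database.

## Command line

```sh
pathtrie synth db --n-graphs 10 --n-vertices 20 --m-edges 40 --seed 1 --out db.gfu
pathtrie synth query --db db.gfu --graph-id 0 --n-edges 4 --seed 1 --out q.gfu
pathtrie build --db db.gfu --out db.idx --lp 4
pathtrie query --db db.gfu --index db.idx --query q.gfu --out results.tsv --stats
```

Graphs travel in a line-based text format: `#name`, vertex count, one label
per line, edge count, one `u v` pair per line.

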
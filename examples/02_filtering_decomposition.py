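"""Watch the two-stage filter decompose a graph into candidate components.

Plants two disjoint copies of a triangle query inside a random host whose
label alphabet the query cannot match, then shows that filtering strips the
host away and hands the matcher two small components — one per copy.
"""

from pathtrie import (
    Database,
    GeneratorConfig,
    LabeledGraph,
    build_index,
    build_query_index,
    candidate_graphs,
    extract_candidate_components,
    match_all,
    matchable_vertices,
    plant_query,
)

query = LabeledGraph(0, "triangle", ["QA", "QB", "QC"], [(0, 1), (1, 2), (0, 2)])
host_cfg = GeneratorConfig(n_vertices=15, m_edges=30, n_labels=3, seed=42)
graph, planted = plant_query(host_cfg, query, n_copies=2, seed=43)

db = Database([graph])
index = build_index(db, lp=3)
query_index = build_query_index(query, lp=3)

print(f"host graph: {graph.n_vertices} vertices, {graph.n_edges} edges")
print(f"candidate graphs: {candidate_graphs(index, query_index)}")

mmap = matchable_vertices(index, query_index, 0)
union = sorted(set().union(*mmap.sets.values()))
print(f"matchable vertices (union): {union}")

components = extract_candidate_components(graph, mmap, query)
print(f"candidate components: {len(components)}")
for i, comp in enumerate(components):
    print(f"  component {i}: vertices {sorted(comp.component.vertex_ids)}")

occurrences = match_all(query, components)
print(f"occurrences: {len(occurrences)}")
for occ in occurrences:
    print(f"  {occ.mapping}")

# The 15 host vertices (labels L0-L2) cannot start any query feature, so
# only the 6 planted vertices survive; the bridge edges run through
# unmatchable host vertices, so each planted triangle becomes its own
# component and yields exactly one occurrence (the query's labels make it
# automorphism-free).
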
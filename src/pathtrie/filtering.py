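"""Two-stage candidate filtering and decomposition into components.

Stage 1 (graph level): a database graph survives only if, for every query
feature, its total path count is at least the query's total count for that
feature.

Stage 2 (vertex level): a data vertex v is *matchable* for query vertex u
only if every feature that starts at u also starts at v, with at least u's
multiplicity.  The union of matchable vertices induces a subgraph of the
candidate; its maximal connected components — after discarding components
too small to host the query or missing some query vertex's matchable
vertices — are the units handed to the matcher.

Both stages read only the tries; no graph is rescanned.  The filter is
sound (it never discards a graph, vertex, or component that carries an
occurrence) but not complete: survivors may contain no occurrence and are
settled by the matching phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .graph_core import Component, LabeledGraph, connected_components, induced_subgraph
from .indexing import DatabaseIndex, TrieNode, build_index
from .graph_core import Database

__all__ = [
    "QueryIndex",
    "MatchableMap",
    "CandidateComponent",
    "build_query_index",
    "candidate_graphs",
    "matchable_vertices",
    "extract_candidate_components",
]

_QUERY_GRAPH_ID = 0


@dataclass
class QueryIndex:
    """The query's own feature trie plus per-vertex feature multiplicities.

    ``per_vertex_features[u]`` maps each label sequence to the number of
    simple paths with that sequence starting at query vertex ``u``.
    """

    query: LabeledGraph
    trie: TrieNode
    per_vertex_features: dict[int, dict[tuple[str, ...], int]]
    lp: int


@dataclass
class MatchableMap:
    """Per-query-vertex sets of compatible data vertices in one graph."""

    graph_id: int
    sets: dict[int, set[int]] = field(default_factory=dict)


@dataclass
class CandidateComponent:
    """One connected piece of a candidate graph with restricted matchable sets."""

    component: Component
    restricted_sets: dict[int, set[int]] = field(default_factory=dict)


def build_query_index(query: LabeledGraph, lp: int) -> QueryIndex:
    """Index the query with the same enumeration semantics as the database.

    The query must be connected (the component decomposition assumes it);
    a disconnected query raises ``ValueError``.
    """
    if query.n_vertices == 0:
        raise ValueError("query has no vertices")
    if len(connected_components(query)) != 1:
        raise ValueError("query graph must be connected")
    pseudo = LabeledGraph(_QUERY_GRAPH_ID, query.name, query.labels, query.edges)
    index = build_index(Database([pseudo]), lp=lp, workers=1)
    per_vertex: dict[int, dict[tuple[str, ...], int]] = {
        u: {} for u in query.vertices()
    }
    for seq, node in index.root.walk():
        for start, count in node.occurrences.get(_QUERY_GRAPH_ID, {}).items():
            per_vertex[start][seq] = count
    return QueryIndex(query=query, trie=index.root, per_vertex_features=per_vertex, lp=lp)


def candidate_graphs(db_index: DatabaseIndex, query_index: QueryIndex) -> list[int]:
    """Graph ids surviving the feature-multiplicity filter, in id order.

    A graph survives iff for every query feature f with total query count
    c(f), the graph's total count for f is >= c(f).  Walking the query trie
    in lockstep with the database trie prunes the surviving set feature by
    feature.
    """
    if db_index.lp != query_index.lp:
        raise ValueError(
            f"index lp mismatch: database {db_index.lp}, query {query_index.lp}"
        )
    alive: set[int] = set(db_index.graph_catalog)

    def descend(qnode: TrieNode, dnode: TrieNode) -> None:
        for label, qchild in qnode.children.items():
            if not alive:
                return
            needed = qchild.total_count(_QUERY_GRAPH_ID)
            dchild = dnode.children.get(label)
            if dchild is None:
                alive.clear()
                return
            survivors = {gid for gid in alive if dchild.total_count(gid) >= needed}
            alive.intersection_update(survivors)
            descend(qchild, dchild)

    descend(query_index.trie, db_index.root)
    return sorted(alive)


def matchable_vertices(
    db_index: DatabaseIndex, query_index: QueryIndex, graph_id: int
) -> MatchableMap:
    """Per-query-vertex matchable sets for one candidate graph.

    v is matchable for u iff for every feature f starting at u with
    multiplicity c_u(f), at least c_u(f) paths with label sequence f start
    at v.  The length-1 feature forces label equality, so every matchable
    set is a subset of the like-labeled vertices.
    """
    sets: dict[int, set[int]] = {}
    for u, features in query_index.per_vertex_features.items():
        # Seed from the depth-1 node (all vertices sharing u's label), then
        # intersect the per-start constraints of every longer feature.
        candidates: set[int] | None = None
        for seq in sorted(features, key=len):
            needed = features[seq]
            node = db_index.root.lookup(seq)
            if node is None:
                candidates = set()
                break
            per_start = node.occurrences.get(graph_id, {})
            passing = {v for v, count in per_start.items() if count >= needed}
            candidates = passing if candidates is None else candidates & passing
            if not candidates:
                break
        sets[u] = candidates or set()
    return MatchableMap(graph_id=graph_id, sets=sets)


def extract_candidate_components(
    graph: LabeledGraph, matchable_map: MatchableMap, query: LabeledGraph
) -> list[CandidateComponent]:
    """Decompose a candidate graph into components worth matching.

    Components of the subgraph induced by the union of matchable vertices
    are kept only if they have at least as many vertices as the query and
    retain a non-empty restriction of every query vertex's matchable set.
    """
    union: set[int] = set()
    for s in matchable_map.sets.values():
        union |= s
    out: list[CandidateComponent] = []
    for block in connected_components(graph, union):
        if len(block) < query.n_vertices:
            continue
        restricted = {u: s & block for u, s in matchable_map.sets.items()}
        if any(not s for s in restricted.values()):
            continue
        out.append(
            CandidateComponent(
                component=induced_subgraph(graph, block),
                restricted_sets=restricted,
            )
        )
    return out
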
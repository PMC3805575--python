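"""Random labeled graphs, edge-growth query extraction, planted copies, and
the brute-force search oracle.

This module stands in for real molecular and interaction-network databases
during development and testing.  The generator draws Erdős–Rényi-style
simple graphs with labels from a small alphabet (uniform or Zipf-skewed, the
skew exercising the long-matchable-list regime); queries are grown from a
random edge of a host graph by repeatedly attaching a random frontier edge,
so every extracted query is connected and occurs in its host by
construction.

``brute_force_search`` is the index-free reference enumerator the test
suite compares the full pipeline against.  It shares no code with the trie,
the filters, or the VF2-style matcher.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

from .graph_core import Database, LabeledGraph
from .matching import Occurrence

__all__ = [
    "GeneratorConfig",
    "random_labeled_graph",
    "extract_query",
    "plant_query",
    "brute_force_search",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of one random labeled graph.

    Exactly one of ``m_edges`` / ``edge_density`` must be given.
    ``label_distribution`` is ``"uniform"``, ``"zipf"`` (weight 1/rank), or
    an explicit weight sequence of length ``n_labels``.
    """

    n_vertices: int
    n_labels: int
    seed: int
    m_edges: int | None = None
    edge_density: float | None = None
    label_distribution: str | Sequence[float] = "uniform"

    def resolved_m_edges(self) -> int:
        max_edges = self.n_vertices * (self.n_vertices - 1) // 2
        if (self.m_edges is None) == (self.edge_density is None):
            raise ValueError("specify exactly one of m_edges or edge_density")
        m = (
            self.m_edges
            if self.m_edges is not None
            else round(self.edge_density * max_edges)
        )
        if not (0 <= m <= max_edges):
            raise ValueError(f"m_edges {m} infeasible for {self.n_vertices} vertices")
        return m


def _label_weights(config: GeneratorConfig) -> list[float]:
    if isinstance(config.label_distribution, str):
        if config.label_distribution == "uniform":
            return [1.0] * config.n_labels
        if config.label_distribution == "zipf":
            return [1.0 / (i + 1) for i in range(config.n_labels)]
        raise ValueError(f"unknown label distribution {config.label_distribution!r}")
    weights = list(config.label_distribution)
    if len(weights) != config.n_labels:
        raise ValueError("label weight vector length must equal n_labels")
    return weights


def random_labeled_graph(
    config: GeneratorConfig, graph_id: int = 0, name: str | None = None
) -> LabeledGraph:
    """Seeded simple undirected graph with random labels.

    Same config (including seed) always yields the identical graph.
    """
    if config.n_vertices < 1:
        raise ValueError("n_vertices must be >= 1")
    rng = random.Random(config.seed)
    m = config.resolved_m_edges()
    alphabet = [f"L{i}" for i in range(config.n_labels)]
    labels = rng.choices(alphabet, weights=_label_weights(config), k=config.n_vertices)
    all_pairs = list(combinations(range(config.n_vertices), 2))
    edges = rng.sample(all_pairs, m)
    return LabeledGraph(
        graph_id, name if name is not None else f"synthetic-{config.seed}", labels, edges
    )


def extract_query(graph: LabeledGraph, n_edges: int, seed: int) -> LabeledGraph:
    """Grow a connected query from the host by random frontier-edge accretion.

    Starting from a uniformly random host edge, repeatedly add a uniformly
    random edge adjacent to the growing subgraph until ``n_edges`` edges are
    collected.  Vertices are renumbered 0..k in order of first appearance;
    labels are copied from the host, so the host contains at least one
    occurrence by construction.  Raises ``ValueError`` if the frontier is
    exhausted early (caller retries with another seed).
    """
    if n_edges < 1:
        raise ValueError("n_edges must be >= 1")
    if graph.n_edges < n_edges:
        raise ValueError(f"host has only {graph.n_edges} edges, need {n_edges}")
    rng = random.Random(seed)
    adjacency = graph.adjacency
    first = sorted(graph.edges)[rng.randrange(graph.n_edges)]
    chosen = {first}
    vertices: list[int] = [first[0], first[1]]
    vset = set(vertices)
    while len(chosen) < n_edges:
        frontier = sorted(
            {
                (min(v, w), max(v, w))
                for v in vset
                for w in adjacency[v]
            }
            - chosen
        )
        if not frontier:
            raise ValueError(
                f"growth exhausted at {len(chosen)} edges before reaching {n_edges}"
            )
        edge = frontier[rng.randrange(len(frontier))]
        chosen.add(edge)
        for v in edge:
            if v not in vset:
                vset.add(v)
                vertices.append(v)
    renumber = {host_v: i for i, host_v in enumerate(vertices)}
    labels = [graph.labels[host_v] for host_v in vertices]
    edges = [(renumber[u], renumber[v]) for u, v in chosen]
    return LabeledGraph(0, f"{graph.name}-query", labels, edges)


def plant_query(
    host_config: GeneratorConfig,
    query: LabeledGraph,
    n_copies: int,
    seed: int,
) -> tuple[LabeledGraph, list[dict[int, int]]]:
    """Random host with vertex-disjoint copies of the query wired in.

    Each copy's vertices are appended after the host's and attached to the
    host by one bridge edge to a random host vertex, keeping the copies in
    one graph without sharing vertices.  Returns the graph and, per copy,
    the planted mapping query vertex -> data vertex.  Make the host's label
    alphabet disjoint from the query's to guarantee the copies survive
    filtering as separate components.
    """
    host = random_labeled_graph(host_config)
    rng = random.Random(seed)
    labels = list(host.labels)
    edges = {tuple(e) for e in host.edges}
    mappings: list[dict[int, int]] = []
    offset = host.n_vertices
    for _ in range(n_copies):
        mapping = {u: offset + u for u in query.vertices()}
        labels.extend(query.labels)
        for u, v in query.edges:
            edges.add((mapping[u], mapping[v]))
        bridge_host = rng.randrange(host.n_vertices)
        bridge_copy = mapping[rng.randrange(query.n_vertices)]
        edges.add((bridge_host, bridge_copy))
        mappings.append(mapping)
        offset += query.n_vertices
    planted = LabeledGraph(host.graph_id, f"{host.name}-planted", labels, edges)
    return planted, mappings


def brute_force_search(database: Database, query: LabeledGraph) -> list[Occurrence]:
    """Index-free exhaustive enumeration of every occurrence.

    Plain backtracking over query vertices in a fixed breadth-first order
    (no tries, no matchable sets, no lookahead); candidates for each query
    vertex are all like-labeled data vertices.  Canonical sort as in
    ``match_all``.
    """
    from .graph_core import connected_components

    if len(connected_components(query)) != 1:
        raise ValueError("query graph must be connected")

    # breadth-first query vertex order starting at 0: each later vertex has
    # at least one earlier neighbor, keeping the partial map connected
    order: list[int] = [0]
    seen = {0}
    q_adj = query.adjacency
    i = 0
    while i < len(order):
        for w in q_adj[order[i]]:
            if w not in seen:
                seen.add(w)
                order.append(w)
        i += 1

    results: list[Occurrence] = []
    for graph in database:
        d_adj = graph.adjacency
        by_label: dict[str, list[int]] = {}
        for v in graph.vertices():
            by_label.setdefault(graph.labels[v], []).append(v)
        mapping: dict[int, int] = {}
        used: set[int] = set()

        def backtrack(depth: int) -> None:
            if depth == len(order):
                results.append(
                    Occurrence(
                        graph_id=graph.graph_id,
                        mapping=tuple(mapping[u] for u in range(query.n_vertices)),
                    )
                )
                return
            u = order[depth]
            for v in by_label.get(query.labels[u], []):
                if v in used:
                    continue
                ok = True
                for w in q_adj[u]:
                    if w in mapping and mapping[w] not in d_adj[v]:
                        ok = False
                        break
                if ok:
                    mapping[u] = v
                    used.add(v)
                    backtrack(depth + 1)
                    del mapping[u]
                    used.discard(v)

        backtrack(0)
    results.sort()
    return results
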
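"""Vertex-labeled undirected graphs, components, and GFU-dialect text I/O.

The data model is the standard one for graph-database search: a database
``D`` is an ordered collection of simple undirected graphs ``G = (V, E, lab)``
where every vertex carries exactly one label from an alphabet of strings.
Vertex ids are 0-based and contiguous within each graph; distinct vertices
may share a label.  Self-loops and parallel edges are rejected.

The GFU dialect is a line-based text format: per graph, a ``#<name>`` header,
the vertex count, one label per line, the edge count, then one ``u v`` pair
per line.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Sequence

__all__ = [
    "LabeledGraph",
    "Component",
    "Database",
    "GFUParseError",
    "read_gfu",
    "write_gfu",
    "connected_components",
    "induced_subgraph",
]


class GFUParseError(ValueError):
    """Malformed GFU input; carries the 1-based line number of the offence."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


def _canonical_edge(u: int, v: int) -> tuple[int, int]:
    return (u, v) if u < v else (v, u)


class LabeledGraph:
    """A simple undirected graph with one string label per vertex.

    Parameters
    ----------
    graph_id:
        Position of the graph in its database (0-based).
    name:
        Free-form name; need not be unique across a database.
    labels:
        Label of vertex ``i`` at position ``i``; all non-empty.
    edges:
        Unordered vertex-id pairs; stored canonically with the smaller
        id first.
    """

    __slots__ = ("graph_id", "name", "labels", "edges", "_adjacency")

    def __init__(
        self,
        graph_id: int,
        name: str,
        labels: Sequence[str],
        edges: Iterable[tuple[int, int]],
    ):
        self.graph_id = int(graph_id)
        self.name = name
        self.labels: tuple[str, ...] = tuple(labels)
        n = len(self.labels)
        canon: set[tuple[int, int]] = set()
        for u, v in edges:
            if u == v:
                raise ValueError(f"self-loop at vertex {u}")
            if not (0 <= u < n and 0 <= v < n):
                raise ValueError(f"edge ({u}, {v}) has endpoint outside 0..{n - 1}")
            canon.add(_canonical_edge(u, v))
        for i, lab in enumerate(self.labels):
            if not lab:
                raise ValueError(f"vertex {i} has an empty label")
        self.edges: frozenset[tuple[int, int]] = frozenset(canon)
        self._adjacency: dict[int, tuple[int, ...]] | None = None

    @property
    def n_vertices(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def adjacency(self) -> dict[int, tuple[int, ...]]:
        """Sorted neighbor tuples per vertex, built lazily and cached."""
        if self._adjacency is None:
            adj: dict[int, list[int]] = {v: [] for v in range(self.n_vertices)}
            for u, v in self.edges:
                adj[u].append(v)
                adj[v].append(u)
            self._adjacency = {v: tuple(sorted(ns)) for v, ns in adj.items()}
        return self._adjacency

    def has_edge(self, u: int, v: int) -> bool:
        return _canonical_edge(u, v) in self.edges

    def vertices(self) -> range:
        return range(self.n_vertices)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LabeledGraph):
            return NotImplemented
        return self.labels == other.labels and self.edges == other.edges

    def __hash__(self) -> int:
        return hash((self.labels, self.edges))

    def __repr__(self) -> str:
        return (
            f"LabeledGraph(graph_id={self.graph_id}, name={self.name!r}, "
            f"|V|={self.n_vertices}, |E|={self.n_edges})"
        )


@dataclass(frozen=True)
class Component:
    """A connected induced subgraph keeping the parent's vertex ids."""

    parent_graph_id: int
    vertex_ids: frozenset[int]
    edges: frozenset[tuple[int, int]]

    @property
    def n_vertices(self) -> int:
        return len(self.vertex_ids)

    def adjacency(self) -> dict[int, tuple[int, ...]]:
        adj: dict[int, list[int]] = {v: [] for v in self.vertex_ids}
        for u, v in self.edges:
            adj[u].append(v)
            adj[v].append(u)
        return {v: tuple(sorted(ns)) for v, ns in adj.items()}


@dataclass
class Database:
    """Ordered sequence of graphs; ``graph_id`` equals position."""

    graphs: list[LabeledGraph] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.graphs)

    def __iter__(self) -> Iterator[LabeledGraph]:
        return iter(self.graphs)

    def __getitem__(self, graph_id: int) -> LabeledGraph:
        return self.graphs[graph_id]

    def append(self, graph: LabeledGraph) -> None:
        if graph.graph_id != len(self.graphs):
            raise ValueError(
                f"graph_id {graph.graph_id} does not match position {len(self.graphs)}"
            )
        self.graphs.append(graph)


def read_gfu(stream: IO[str]) -> Database:
    """Parse zero or more GFU records into a :class:`Database`.

    Duplicate edge lines collapse to a single edge.  Malformed input raises
    :class:`GFUParseError` naming the offending line.
    """
    lines = stream.read().splitlines()
    pos = 0
    n_lines = len(lines)

    def next_line() -> tuple[str, int]:
        nonlocal pos
        while pos < n_lines and lines[pos].strip() == "":
            pos += 1
        if pos >= n_lines:
            raise GFUParseError("unexpected end of input", n_lines)
        line = lines[pos]
        pos += 1
        return line, pos  # pos is now the 1-based number of the returned line

    db = Database()
    while True:
        # skip trailing blank lines between records / at EOF
        while pos < n_lines and lines[pos].strip() == "":
            pos += 1
        if pos >= n_lines:
            break
        header, lineno = next_line()
        header = header.strip()
        if not header.startswith("#"):
            raise GFUParseError(f"expected '#<name>' header, got {header!r}", lineno)
        name = header[1:]
        count_line, lineno = next_line()
        try:
            n_vertices = int(count_line.strip())
        except ValueError:
            raise GFUParseError(f"bad vertex count {count_line.strip()!r}", lineno) from None
        if n_vertices < 0:
            raise GFUParseError(f"negative vertex count {n_vertices}", lineno)
        labels: list[str] = []
        for _ in range(n_vertices):
            raw, lineno = next_line()
            label = raw.strip()
            if not label:
                raise GFUParseError("empty label line", lineno)
            labels.append(label)
        count_line, lineno = next_line()
        try:
            n_edges = int(count_line.strip())
        except ValueError:
            raise GFUParseError(f"bad edge count {count_line.strip()!r}", lineno) from None
        if n_edges < 0:
            raise GFUParseError(f"negative edge count {n_edges}", lineno)
        edges: set[tuple[int, int]] = set()
        for _ in range(n_edges):
            raw, lineno = next_line()
            parts = raw.split()
            if len(parts) != 2:
                raise GFUParseError(f"expected 'u v' edge line, got {raw!r}", lineno)
            try:
                u, v = int(parts[0]), int(parts[1])
            except ValueError:
                raise GFUParseError(f"non-integer edge endpoints {raw!r}", lineno) from None
            if u == v:
                raise GFUParseError(f"self-loop '{u} {v}'", lineno)
            if not (0 <= u < n_vertices and 0 <= v < n_vertices):
                raise GFUParseError(
                    f"edge endpoint out of range in '{u} {v}' (N={n_vertices})", lineno
                )
            edges.add(_canonical_edge(u, v))
        db.append(LabeledGraph(len(db), name, labels, edges))
    return db


def write_gfu(database: Database, stream: IO[str]) -> None:
    """Write the database in canonical GFU form (sorted edges, LF newlines)."""
    for g in database:
        stream.write(f"#{g.name}\n")
        stream.write(f"{g.n_vertices}\n")
        for label in g.labels:
            stream.write(f"{label}\n")
        stream.write(f"{g.n_edges}\n")
        for u, v in sorted(g.edges):
            stream.write(f"{u} {v}\n")


def connected_components(
    graph: LabeledGraph, subset: Iterable[int] | None = None
) -> list[set[int]]:
    """Maximal connected vertex sets of the subgraph induced by ``subset``.

    Only edges with both endpoints inside the subset connect vertices.
    Components are returned ordered by their smallest contained vertex id.
    """
    allowed = set(graph.vertices()) if subset is None else set(subset)
    adjacency = graph.adjacency
    seen: set[int] = set()
    components: list[set[int]] = []
    for start in sorted(allowed):
        if start in seen:
            continue
        comp = {start}
        queue = deque([start])
        seen.add(start)
        while queue:
            v = queue.popleft()
            for w in adjacency[v]:
                if w in allowed and w not in seen:
                    seen.add(w)
                    comp.add(w)
                    queue.append(w)
        components.append(comp)
    return components


def induced_subgraph(graph: LabeledGraph, vertex_ids: Iterable[int]) -> Component:
    """Induced, connected subgraph on ``vertex_ids`` with parent ids kept.

    Raises ``ValueError`` if the vertex set is not connected in the induced
    sense (the contract is that callers pass one block of
    :func:`connected_components`).
    """
    vset = frozenset(vertex_ids)
    for v in vset:
        if not (0 <= v < graph.n_vertices):
            raise ValueError(f"vertex {v} not in parent graph")
    edges = frozenset(e for e in graph.edges if e[0] in vset and e[1] in vset)
    blocks = connected_components(graph, vset)
    if len(blocks) != 1:
        raise ValueError(f"vertex set {sorted(vset)} induces {len(blocks)} components")
    return Component(parent_graph_id=graph.graph_id, vertex_ids=vset, edges=edges)
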
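"""Path-trie index construction over a database of labeled graphs.

A *feature* is the label sequence of a vertex-simple path of at most ``lp``
edges (a path of k edges has k+1 labels).  Every feature of every graph is
inserted into a prefix tree whose root is virtual; each trie node records,
per graph and per start vertex, how many simple paths realize the node's
label sequence from that start.  Because every prefix of an enumerated path
is itself a feature, the trie answers all feature lengths up to ``lp`` at
once.

Construction parallelizes over (graph, same-label vertex list) work units;
partial tries are merged sequentially, and the merged result is independent
of worker count and merge order.
"""

from __future__ import annotations

import json
import multiprocessing
from dataclasses import dataclass, field
from typing import IO, Iterator, Sequence

from .graph_core import Database, LabeledGraph

__all__ = [
    "TrieNode",
    "DatabaseIndex",
    "IndexFormatError",
    "MIN_LP",
    "MAX_LP",
    "DEFAULT_LP",
    "enumerate_label_paths",
    "group_vertices_by_label",
    "build_partial_trie",
    "merge_trie",
    "build_index",
    "save_index",
    "load_index",
]

MIN_LP = 1
MAX_LP = 10
DEFAULT_LP = 4

_FORMAT_MAGIC = "pathtrie-index"
_FORMAT_VERSION = 1


class IndexFormatError(ValueError):
    """Raised when a persisted index cannot be loaded."""


class TrieNode:
    """One node of the feature trie.

    ``occurrences`` maps graph_id -> {start_vertex -> path_count}: how many
    simple paths with this node's label sequence start at each vertex of
    each graph.  The root is virtual (``label`` is ``None``) and carries no
    occurrences.
    """

    __slots__ = ("label", "children", "occurrences")

    def __init__(self, label: str | None = None):
        self.label = label
        self.children: dict[str, TrieNode] = {}
        self.occurrences: dict[int, dict[int, int]] = {}

    def child(self, label: str) -> TrieNode | None:
        return self.children.get(label)

    def ensure_child(self, label: str) -> TrieNode:
        node = self.children.get(label)
        if node is None:
            node = TrieNode(label)
            self.children[label] = node
        return node

    def record(self, graph_id: int, start_vertex: int, count: int = 1) -> None:
        per_start = self.occurrences.setdefault(graph_id, {})
        per_start[start_vertex] = per_start.get(start_vertex, 0) + count

    def total_count(self, graph_id: int) -> int:
        """Total number of paths with this feature in one graph."""
        return sum(self.occurrences.get(graph_id, {}).values())

    def walk(self, prefix: tuple[str, ...] = ()) -> Iterator[tuple[tuple[str, ...], "TrieNode"]]:
        """Preorder traversal yielding (label sequence, node), root excluded."""
        for label in sorted(self.children):
            node = self.children[label]
            seq = prefix + (label,)
            yield seq, node
            yield from node.walk(seq)

    def lookup(self, label_seq: Sequence[str]) -> "TrieNode | None":
        node: TrieNode | None = self
        for label in label_seq:
            node = node.children.get(label) if node is not None else None
            if node is None:
                return None
        return node

    def structurally_equal(self, other: "TrieNode") -> bool:
        if self.label != other.label or self.occurrences != other.occurrences:
            return False
        if set(self.children) != set(other.children):
            return False
        return all(
            child.structurally_equal(other.children[label])
            for label, child in self.children.items()
        )

    def __repr__(self) -> str:
        return f"TrieNode(label={self.label!r}, children={sorted(self.children)})"


@dataclass
class DatabaseIndex:
    """Global feature trie over a database plus a graph catalog."""

    lp: int
    root: TrieNode
    graph_catalog: dict[int, tuple[str, int, int]] = field(default_factory=dict)

    def structurally_equal(self, other: "DatabaseIndex") -> bool:
        return (
            self.lp == other.lp
            and self.graph_catalog == other.graph_catalog
            and self.root.structurally_equal(other.root)
        )


def enumerate_label_paths(
    graph: LabeledGraph, start_vertex: int, lp: int
) -> Iterator[tuple[tuple[str, ...], int]]:
    """Yield (label sequence, start vertex) for every simple path of 0..lp
    edges beginning at ``start_vertex``.

    Paths are vertex-simple; each distinct vertex path yields once, so the
    same label sequence may appear multiple times.  Every prefix of a longer
    path is yielded in its own right (it is a shorter path).
    """
    if not (0 <= start_vertex < graph.n_vertices):
        raise ValueError(f"start vertex {start_vertex} out of range")
    labels = graph.labels
    adjacency = graph.adjacency
    path_labels = [labels[start_vertex]]
    on_path = {start_vertex}

    def dfs(v: int, depth: int) -> Iterator[tuple[tuple[str, ...], int]]:
        yield tuple(path_labels), start_vertex
        if depth == lp:
            return
        for w in adjacency[v]:
            if w in on_path:
                continue
            on_path.add(w)
            path_labels.append(labels[w])
            yield from dfs(w, depth + 1)
            path_labels.pop()
            on_path.discard(w)

    yield from dfs(start_vertex, 0)


def group_vertices_by_label(graph: LabeledGraph) -> dict[str, list[int]]:
    """Partition the vertex set by label; these lists are the parallel work units."""
    groups: dict[str, list[int]] = {}
    for v in graph.vertices():
        groups.setdefault(graph.labels[v], []).append(v)
    return groups


def build_partial_trie(graph: LabeledGraph, vertex_list: Sequence[int], lp: int) -> TrieNode:
    """Trie of all features starting at the listed vertices of one graph."""
    root = TrieNode()
    gid = graph.graph_id
    labels = graph.labels
    adjacency = graph.adjacency
    for start in vertex_list:
        # Inline DFS carrying the trie cursor: records the node for every
        # prefix as the path grows, without materializing label tuples.
        on_path = {start}

        def dfs(v: int, node: TrieNode, depth: int) -> None:
            node.record(gid, start)
            if depth == lp:
                return
            for w in adjacency[v]:
                if w in on_path:
                    continue
                on_path.add(w)
                dfs(w, node.ensure_child(labels[w]), depth + 1)
                on_path.discard(w)

        dfs(start, root.ensure_child(labels[start]), 0)
    return root


def merge_trie(accumulator: TrieNode, other: TrieNode) -> TrieNode:
    """Node-wise union into ``accumulator``; per-graph per-start counts add.

    Commutative and associative up to structural equality, so the global
    trie does not depend on the order partial tries arrive in.
    """
    for gid, per_start in other.occurrences.items():
        acc_per_start = accumulator.occurrences.setdefault(gid, {})
        for start, count in per_start.items():
            acc_per_start[start] = acc_per_start.get(start, 0) + count
    for label, child in other.children.items():
        merge_trie(accumulator.ensure_child(label), child)
    return accumulator


def _validate_lp(lp: int) -> None:
    if not (MIN_LP <= lp <= MAX_LP):
        raise ValueError(f"lp must be in {MIN_LP}..{MAX_LP}, got {lp}")


def _partial_trie_task(args: tuple[LabeledGraph, list[int], int]) -> TrieNode:
    graph, vertex_list, lp = args
    return build_partial_trie(graph, vertex_list, lp)


def build_index(database: Database, lp: int = DEFAULT_LP, workers: int = 1) -> DatabaseIndex:
    """Build the global trie over all graphs.

    Work units are (graph, same-label vertex list) pairs; with ``workers > 1``
    they are dispatched to a dynamic process pool and the partial tries are
    merged sequentially.  The logical content of the result is identical for
    any worker count.
    """
    _validate_lp(lp)
    if workers < 1:
        raise ValueError(f"workers must be >= 1, got {workers}")
    tasks = [
        (graph, vertex_list, lp)
        for graph in database
        for _, vertex_list in sorted(group_vertices_by_label(graph).items())
    ]
    root = TrieNode()
    if workers == 1 or len(tasks) <= 1:
        for task in tasks:
            merge_trie(root, _partial_trie_task(task))
    else:
        ctx = multiprocessing.get_context("fork")
        with ctx.Pool(processes=workers) as pool:
            for partial in pool.imap_unordered(_partial_trie_task, tasks, chunksize=1):
                merge_trie(root, partial)
    catalog = {g.graph_id: (g.name, g.n_vertices, g.n_edges) for g in database}
    return DatabaseIndex(lp=lp, root=root, graph_catalog=catalog)


def _node_to_json(node: TrieNode) -> dict:
    return {
        "occ": {
            str(gid): {str(v): c for v, c in sorted(per_start.items())}
            for gid, per_start in sorted(node.occurrences.items())
        },
        "children": {
            label: _node_to_json(node.children[label]) for label in sorted(node.children)
        },
    }


def _node_from_json(label: str | None, payload: dict) -> TrieNode:
    node = TrieNode(label)
    node.occurrences = {
        int(gid): {int(v): int(c) for v, c in per_start.items()}
        for gid, per_start in payload.get("occ", {}).items()
    }
    node.children = {
        lab: _node_from_json(lab, child) for lab, child in payload.get("children", {}).items()
    }
    return node


def save_index(index: DatabaseIndex, stream: IO[str]) -> None:
    """Persist the index as a versioned JSON container."""
    payload = {
        "magic": _FORMAT_MAGIC,
        "format_version": _FORMAT_VERSION,
        "lp": index.lp,
        "n_graphs": len(index.graph_catalog),
        "catalog": {
            str(gid): list(entry) for gid, entry in sorted(index.graph_catalog.items())
        },
        "trie": _node_to_json(index.root),
    }
    json.dump(payload, stream, separators=(",", ":"))
    stream.write("\n")


def load_index(stream: IO[str]) -> DatabaseIndex:
    """Load a persisted index; rejects wrong magic, version, or truncation."""
    try:
        payload = json.load(stream)
    except json.JSONDecodeError as exc:
        raise IndexFormatError(f"corrupt or truncated index file: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("magic") != _FORMAT_MAGIC:
        raise IndexFormatError("not a pathtrie index file (bad magic header)")
    version = payload.get("format_version")
    if version != _FORMAT_VERSION:
        raise IndexFormatError(
            f"unsupported index format version {version!r} (expected {_FORMAT_VERSION})"
        )
    lp = int(payload["lp"])
    _validate_lp(lp)
    catalog = {
        int(gid): (entry[0], int(entry[1]), int(entry[2]))
        for gid, entry in payload.get("catalog", {}).items()
    }
    root = _node_from_json(None, payload.get("trie", {}))
    return DatabaseIndex(lp=lp, root=root, graph_catalog=catalog)
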
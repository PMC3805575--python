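"""Exhaustive subgraph-monomorphism enumeration over candidate components.

The matcher is a VF2-style backtracking search: states are partial injective
mappings of query vertices to data vertices, extended one pair at a time and
pruned by feasibility rules — label equality, edge consistency with already
mapped neighbors, membership in the component's restricted matchable set,
and a lookahead comparing unmapped-neighbor counts.  Because the semantics
are monomorphism (data edges outside the image are allowed), the lookahead
is one-sided: the query side must not exceed the data side.

Parallelism follows the seed-task scheme: for each component, one task per
(root query vertex, seed data vertex) pair, where the root is the query
vertex with the longest restricted list.  Every occurrence maps the root to
exactly one seed, so the tasks partition the match space and the union of
their outputs, sorted canonically, is independent of scheduling.
"""

from __future__ import annotations

import multiprocessing
from dataclasses import dataclass

from .filtering import CandidateComponent
from .graph_core import LabeledGraph

__all__ = [
    "Occurrence",
    "MatchTask",
    "choose_root_vertex",
    "make_match_tasks",
    "vf2_enumerate",
    "match_all",
]


@dataclass(frozen=True, order=True)
class Occurrence:
    """One injective, label-preserving, edge-preserving embedding.

    ``mapping[u]`` is the data vertex image of query vertex ``u``; the
    canonical sort key is (graph_id, mapping tuple).
    """

    graph_id: int
    mapping: tuple[int, ...]

    def as_dict(self) -> dict[int, int]:
        return dict(enumerate(self.mapping))


@dataclass(frozen=True)
class MatchTask:
    """A matcher instance pinned to one (root query vertex, seed) pair."""

    candidate_component: CandidateComponent
    root_query_vertex: int
    seed_data_vertex: int


def choose_root_vertex(query: LabeledGraph, candidate_component: CandidateComponent) -> int:
    """Query vertex with the largest restricted set (longest seed list);
    ties broken by smallest query vertex id."""
    sets = candidate_component.restricted_sets
    return max(query.vertices(), key=lambda u: (len(sets[u]), -u))


def make_match_tasks(
    query: LabeledGraph, candidate_components: list[CandidateComponent]
) -> list[MatchTask]:
    """One task per (component, seed), seeds drawn from the root's restricted
    set.  Longer root lists come first (they offer the most parallelism),
    then component order, then ascending seed id."""
    keyed: list[tuple[int, int, int, MatchTask]] = []
    for comp_pos, comp in enumerate(candidate_components):
        root = choose_root_vertex(query, comp)
        size = len(comp.restricted_sets[root])
        for seed in sorted(comp.restricted_sets[root]):
            keyed.append((-size, comp_pos, seed, MatchTask(comp, root, seed)))
    keyed.sort(key=lambda item: item[:3])
    return [task for *_, task in keyed]


def vf2_enumerate(
    task: MatchTask, query: LabeledGraph, count_only: bool = False
) -> list[Occurrence] | int:
    """All occurrences whose root maps to the task's seed.

    Output is sorted lexicographically by the mapping's data-vertex tuple
    in query-vertex order.  With ``count_only`` the occurrence count is
    returned instead of materialized mappings.
    """
    comp = task.candidate_component
    component = comp.component
    restricted = comp.restricted_sets
    q_adj = query.adjacency
    d_adj = component.adjacency()
    n_query = query.n_vertices

    root = task.root_query_vertex
    seed = task.seed_data_vertex
    if seed not in restricted[root]:
        return 0 if count_only else []

    mapping: dict[int, int] = {root: seed}
    used: set[int] = {seed}
    results: list[Occurrence] = []
    count = 0

    def next_query_vertex() -> int:
        # Among unmapped query vertices adjacent to the mapped frontier,
        # take the one with the smallest restricted set, tie-break by id.
        best = -1
        best_key: tuple[int, int] | None = None
        for u in mapping:
            for w in q_adj[u]:
                if w in mapping:
                    continue
                key = (len(restricted[w]), w)
                if best_key is None or key < best_key:
                    best_key = key
                    best = w
        return best

    def feasible(u: int, v: int) -> bool:
        if v in used or v not in restricted[u]:
            return False
        v_neighbors = d_adj[v]
        for w in q_adj[u]:
            mapped = mapping.get(w)
            if mapped is not None and mapped not in v_neighbors:
                return False
        # Monomorphism lookahead: u's unmapped query neighbors must fit
        # among v's unused data neighbors.
        q_free = sum(1 for w in q_adj[u] if w not in mapping)
        d_free = sum(1 for x in v_neighbors if x not in used)
        return q_free <= d_free

    def extend() -> None:
        nonlocal count
        if len(mapping) == n_query:
            if count_only:
                count += 1
            else:
                results.append(
                    Occurrence(
                        graph_id=component.parent_graph_id,
                        mapping=tuple(mapping[u] for u in range(n_query)),
                    )
                )
            return
        u = next_query_vertex()
        for v in sorted(restricted[u]):
            if feasible(u, v):
                mapping[u] = v
                used.add(v)
                extend()
                del mapping[u]
                used.discard(v)

    extend()
    if count_only:
        return count
    results.sort()
    return results


def match_all(
    query: LabeledGraph,
    candidate_components: list[CandidateComponent],
    workers: int = 1,
    count_only: bool = False,
) -> list[Occurrence] | int:
    """Union over all seed tasks, canonically sorted by (graph_id, mapping).

    With ``workers > 1`` tasks run on a dynamic process pool; results are
    merged and re-sorted so the output is identical for any worker count.
    With ``count_only`` the total occurrence count is returned.
    """
    if workers < 1:
        raise ValueError(f"workers must be >= 1, got {workers}")
    tasks = make_match_tasks(query, candidate_components)
    partials: list[list[Occurrence] | int]
    if workers == 1 or len(tasks) <= 1:
        partials = [vf2_enumerate(t, query, count_only) for t in tasks]
    else:
        ctx = multiprocessing.get_context("fork")
        with ctx.Pool(processes=workers) as pool:
            partials = pool.map(
                _run_task_payload,
                [(t, query, count_only) for t in tasks],
                chunksize=1,
            )
    if count_only:
        return sum(partials)  # type: ignore[arg-type]
    merged: list[Occurrence] = []
    for part in partials:
        merged.extend(part)  # type: ignore[arg-type]
    merged.sort()
    return merged


def _run_task_payload(args: tuple[MatchTask, LabeledGraph, bool]) -> list[Occurrence] | int:
    task, query, count_only = args
    return vf2_enumerate(task, query, count_only)
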
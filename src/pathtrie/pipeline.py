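"""End-to-end query pipeline: filter candidates, decompose, match, report.

Ties the three phases together.  The building phase produces the global
trie once per database; each query then (1) builds its own index with the
database index's ``lp``, (2) filters graphs and vertices, (3) decomposes
candidates into components, and (4) enumerates occurrences.  Filtering is
cheap relative to matching and its time is folded into the matching phase
in the reported timings.

The output contract is deterministic: occurrence order, the results TSV,
and all counters are identical for any worker count and across repeated
runs on the same inputs.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import IO

from .filtering import (
    CandidateComponent,
    build_query_index,
    candidate_graphs,
    extract_candidate_components,
    matchable_vertices,
)
from .graph_core import Database, LabeledGraph
from .indexing import DatabaseIndex
from .matching import Occurrence, match_all

__all__ = ["QueryResult", "run_query", "write_results_tsv", "check_catalog"]


@dataclass
class QueryResult:
    """Occurrences plus the per-phase counters of one query run."""

    occurrences: list[Occurrence] = field(default_factory=list)
    n_db_graphs: int = 0
    n_candidates: int = 0
    n_components: int = 0
    n_occurrences: int = 0
    count_only: bool = False
    timings: dict[str, float] = field(default_factory=dict)

    def per_graph(self) -> dict[int, list[Occurrence]]:
        out: dict[int, list[Occurrence]] = {}
        for occ in self.occurrences:
            out.setdefault(occ.graph_id, []).append(occ)
        return out

    def stats_lines(self) -> list[str]:
        lines = [
            f"n_db_graphs={self.n_db_graphs}",
            f"n_candidates={self.n_candidates}",
            f"n_components={self.n_components}",
            f"n_occurrences={self.n_occurrences}",
        ]
        lines.extend(f"time_{k}={v:.4f}" for k, v in self.timings.items())
        return lines


def check_catalog(database: Database, index: DatabaseIndex) -> None:
    """Verify a database file matches the catalog the index was built from."""
    if len(database) != len(index.graph_catalog):
        raise ValueError(
            f"database has {len(database)} graphs but index catalog has "
            f"{len(index.graph_catalog)}"
        )
    for g in database:
        entry = index.graph_catalog.get(g.graph_id)
        if entry != (g.name, g.n_vertices, g.n_edges):
            raise ValueError(
                f"graph {g.graph_id} ({g.name!r}) does not match index catalog entry {entry!r}"
            )


def run_query(
    database: Database,
    index: DatabaseIndex,
    query: LabeledGraph,
    workers: int = 1,
    count_only: bool = False,
) -> QueryResult:
    """Run filtering + matching for one connected query.

    The query's features are enumerated with the *index's* ``lp``.  Returns
    all occurrences sorted by (graph_id, mapping); with ``count_only`` the
    mappings are not materialized and only counters are filled.
    """
    t0 = time.perf_counter()
    query_index = build_query_index(query, lp=index.lp)
    candidates = candidate_graphs(index, query_index)
    components: list[CandidateComponent] = []
    for gid in candidates:
        mmap = matchable_vertices(index, query_index, gid)
        components.extend(extract_candidate_components(database[gid], mmap, query))
    t1 = time.perf_counter()
    matched = match_all(query, components, workers=workers, count_only=count_only)
    t2 = time.perf_counter()

    result = QueryResult(
        n_db_graphs=len(database),
        n_candidates=len(candidates),
        n_components=len(components),
        count_only=count_only,
        # filtering time folded into the matching phase
        timings={"matching": t2 - t0, "filtering_included": t1 - t0},
    )
    if count_only:
        result.n_occurrences = matched  # type: ignore[assignment]
    else:
        result.occurrences = matched  # type: ignore[assignment]
        result.n_occurrences = len(result.occurrences)
    return result


def write_results_tsv(result: QueryResult, database: Database, stream: IO[str]) -> None:
    """One line per occurrence:
    graph_id, graph_name, per-graph ordinal, semicolon-joined ``q->v`` pairs
    in query-vertex order."""
    ordinal = 0
    current_gid: int | None = None
    for occ in result.occurrences:
        if occ.graph_id != current_gid:
            current_gid = occ.graph_id
            ordinal = 0
        pairs = ";".join(f"{u}->{v}" for u, v in enumerate(occ.mapping))
        stream.write(f"{occ.graph_id}\t{database[occ.graph_id].name}\t{ordinal}\t{pairs}\n")
        ordinal += 1
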
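"""Build a path-trie index over a tiny database and search a query.

Constructs two small labeled graphs, indexes them with paths of up to 3
edges, and enumerates every occurrence of a 3-vertex query.
"""

import io

from pathtrie import (
    Database,
    build_index,
    read_gfu,
    run_query,
    write_results_tsv,
)

DB_TEXT = """\
#molecule-1
4
C
N
C
O
4
0 1
1 2
2 3
0 2
#molecule-2
3
C
N
C
2
0 1
1 2
"""

QUERY_TEXT = """\
#probe
3
C
N
C
2
0 1
1 2
"""

db = read_gfu(io.StringIO(DB_TEXT))
query = read_gfu(io.StringIO(QUERY_TEXT))[0]

index = build_index(db, lp=3)
result = run_query(db, index, query)

print(f"database graphs : {result.n_db_graphs}")
print(f"candidates      : {result.n_candidates}")
print(f"components      : {result.n_components}")
print(f"occurrences     : {result.n_occurrences}")
out = io.StringIO()
write_results_tsv(result, db, out)
print(out.getvalue(), end="")

# Each TSV line is one occurrence: graph id, graph name, per-graph ordinal,
# and the query-vertex -> data-vertex mapping.  The C-N-C probe fits both
# ways around in each graph, so each contributes two occurrences.
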
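import random

import pytest

from pathtrie.graph_core import Database, LabeledGraph
from pathtrie.synthetic import GeneratorConfig, extract_query, random_labeled_graph


def make_graph(labels, edges, graph_id=0, name="g"):
    return LabeledGraph(graph_id, name, labels, edges)


@pytest.fixture
def path_aba():
    """Path graph A(0)-B(1)-A(2)."""
    return make_graph(["A", "B", "A"], [(0, 1), (1, 2)])


@pytest.fixture
def triangle_abc():
    return make_graph(["A", "B", "C"], [(0, 1), (1, 2), (0, 2)])


def k_n(n, label="A"):
    """Complete graph on n vertices, single label."""
    return make_graph([label] * n, [(i, j) for i in range(n) for j in range(i + 1, n)])


def random_trial(seed, n_graphs=None, query_edges=None):
    """One seeded (database, query) pair inside the default test envelope:
    10-20 graphs of 10-30 vertices, 2-6 labels, queries of 4/8/16 edges.
    The query is extracted from a random database graph, so at least one
    occurrence exists."""
    rng = random.Random(seed)
    if n_graphs is None:
        n_graphs = rng.randint(10, 20)
    graphs = []
    for i in range(n_graphs):
        n = rng.randint(10, 30)
        m = rng.randint(n, 2 * n)
        cfg = GeneratorConfig(
            n_vertices=n,
            m_edges=min(m, n * (n - 1) // 2),
            n_labels=rng.randint(2, 6),
            seed=rng.randrange(2**31),
            label_distribution=rng.choice(["uniform", "zipf"]),
        )
        graphs.append(random_labeled_graph(cfg, graph_id=i, name=f"g{i}"))
    db = Database(graphs)
    if query_edges is None:
        query_edges = rng.choice([4, 8, 16])
    host = db[rng.randrange(n_graphs)]
    while True:
        try:
            query = extract_query(host, min(query_edges, host.n_edges), rng.randrange(2**31))
            return db, query
        except ValueError:
            host = db[rng.randrange(n_graphs)]
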
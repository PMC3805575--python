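import io
import random
from collections import Counter

import pytest

from pathtrie.graph_core import Database
from pathtrie.indexing import (
    IndexFormatError,
    TrieNode,
    build_index,
    build_partial_trie,
    enumerate_label_paths,
    group_vertices_by_label,
    load_index,
    merge_trie,
    save_index,
)
from pathtrie.synthetic import GeneratorConfig, random_labeled_graph

from conftest import make_graph


def brute_force_simple_paths(graph, max_edges):
    """Independent path counter: enumerate every vertex-simple path of
    0..max_edges edges by plain recursion over vertex sequences and count
    label sequences per (sequence, start vertex)."""
    counts = Counter()

    def extend(path):
        seq = tuple(graph.labels[v] for v in path)
        counts[(seq, path[0])] += 1
        if len(path) - 1 == max_edges:
            return
        for w in graph.adjacency[path[-1]]:
            if w not in path:
                extend(path + [w])

    for v in graph.vertices():
        extend([v])
    return counts


class TestEnumerateLabelPaths:
    def test_path_graph(self, path_aba):
        items = sorted(enumerate_label_paths(path_aba, 0, 2))
        assert items == [(("A",), 0), (("A", "B"), 0), (("A", "B", "A"), 0)]

    def test_isolated_vertex(self):
        g = make_graph(["X"], [])
        assert list(enumerate_label_paths(g, 0, 5)) == [(("X",), 0)]

    def test_triangle_all_simple_paths(self, triangle_abc):
        seqs = sorted(seq for seq, _ in enumerate_label_paths(triangle_abc, 0, 2))
        assert seqs == [
            ("A",),
            ("A", "B"),
            ("A", "B", "C"),
            ("A", "C"),
            ("A", "C", "B"),
        ]

    def test_no_repeated_vertices(self):
        # square with all labels equal: lp 3 paths never revisit a vertex
        g = make_graph(["A"] * 4, [(0, 1), (1, 2), (2, 3), (3, 0)])
        for seq, _ in enumerate_label_paths(g, 0, 3):
            assert len(seq) <= 4


class TestGroupVerticesByLabel:
    def test_basic(self, path_aba):
        assert group_vertices_by_label(path_aba) == {"A": [0, 2], "B": [1]}

    def test_all_distinct(self, triangle_abc):
        groups = group_vertices_by_label(triangle_abc)
        assert all(len(v) == 1 for v in groups.values())

    def test_single_label(self):
        g = make_graph(["Z"] * 5, [(i, i + 1) for i in range(4)])
        assert group_vertices_by_label(g) == {"Z": [0, 1, 2, 3, 4]}


class TestPartialTrieAndMerge:
    def test_path_graph_label_a_list(self, path_aba):
        trie = build_partial_trie(path_aba, [0, 2], 2)
        assert trie.lookup(["A"]).occurrences == {0: {0: 1, 2: 1}}
        assert trie.lookup(["A", "B"]).occurrences == {0: {0: 1, 2: 1}}
        assert trie.lookup(["A", "B", "A"]).occurrences == {0: {0: 1, 2: 1}}
        assert trie.lookup(["B"]) is None

    def test_empty_vertex_list(self, path_aba):
        trie = build_partial_trie(path_aba, [], 2)
        assert trie.children == {}

    def test_star_center_only(self):
        g = make_graph(["A", "B", "B", "B"], [(0, 1), (0, 2), (0, 3)])
        trie = build_partial_trie(g, [0], 2)
        assert trie.lookup(["A"]).occurrences == {0: {0: 1}}
        assert trie.lookup(["A", "B"]).occurrences == {0: {0: 3}}
        # leaves have no unvisited neighbor beyond the center
        assert trie.lookup(["A", "B"]).children == {}

    def test_merge_identity(self, path_aba):
        t = build_partial_trie(path_aba, [0, 2], 2)
        merged = merge_trie(TrieNode(), t)
        assert merged.structurally_equal(t)

    def test_merge_of_label_lists_equals_full_build(self, triangle_abc):
        full = build_partial_trie(triangle_abc, [0, 1, 2], 2)
        acc = TrieNode()
        for _, vertex_list in sorted(group_vertices_by_label(triangle_abc).items()):
            merge_trie(acc, build_partial_trie(triangle_abc, vertex_list, 2))
        assert acc.structurally_equal(full)

    def test_merge_order_invariance(self, path_aba, triangle_abc):
        t1 = build_partial_trie(path_aba, [0, 2], 2)
        t2 = build_partial_trie(path_aba, [1], 2)
        a = merge_trie(merge_trie(TrieNode(), t1), t2)
        b = merge_trie(merge_trie(TrieNode(), t2), t1)
        assert a.structurally_equal(b)


class TestBuildIndex:
    def test_matches_hand_built_tries(self, path_aba):
        index = build_index(Database([path_aba]), lp=2)
        expected = TrieNode()
        for _, vl in sorted(group_vertices_by_label(path_aba).items()):
            merge_trie(expected, build_partial_trie(path_aba, vl, 2))
        assert index.root.structurally_equal(expected)
        assert index.graph_catalog == {0: ("g", 3, 2)}

    def test_duplicate_graphs_symmetric_occurrences(self, path_aba):
        twin = make_graph(list(path_aba.labels), path_aba.edges, graph_id=1)
        index = build_index(Database([path_aba, twin]), lp=2)
        for _, node in index.root.walk():
            assert node.occurrences.get(0) == node.occurrences.get(1)

    @pytest.mark.parametrize("lp", [0, 11])
    def test_invalid_lp_rejected(self, path_aba, lp):
        with pytest.raises(ValueError, match="lp"):
            build_index(Database([path_aba]), lp=lp)

    def test_worker_count_invariance(self):
        rng = random.Random(7)
        graphs = [
            random_labeled_graph(
                GeneratorConfig(
                    n_vertices=rng.randint(8, 14),
                    m_edges=rng.randint(10, 20),
                    n_labels=3,
                    seed=rng.randrange(2**31),
                ),
                graph_id=i,
                name=f"g{i}",
            )
            for i in range(20)
        ]
        db = Database(graphs)
        serial = build_index(db, lp=3, workers=1)
        parallel = build_index(db, lp=3, workers=4)
        assert serial.structurally_equal(parallel)
        a, b = io.StringIO(), io.StringIO()
        save_index(serial, a)
        save_index(parallel, b)
        assert a.getvalue() == b.getvalue()


class TestTrieCountsAgainstBruteForce:
    @pytest.mark.parametrize("seed", range(12))
    def test_per_node_counts_equal_simple_path_counts(self, seed):
        """Per-node, per-graph, per-start counts equal exhaustive simple-path
        enumeration on small random graphs."""
        rng = random.Random(seed)
        n = rng.randint(2, 8)
        g = random_labeled_graph(
            GeneratorConfig(
                n_vertices=n,
                m_edges=rng.randint(1, n * (n - 1) // 2),
                n_labels=rng.randint(1, 3),
                seed=seed,
            )
        )
        lp = rng.randint(1, 4)
        index = build_index(Database([g]), lp=lp)
        expected = brute_force_simple_paths(g, lp)
        got = Counter()
        for seq, node in index.root.walk():
            for start, count in node.occurrences.get(0, {}).items():
                got[(seq, start)] = count
        assert got == +expected

    def test_depth1_counts_are_label_histogram(self, path_aba):
        index = build_index(Database([path_aba]), lp=2)
        depth1 = {
            label: node.total_count(0) for label, node in index.root.children.items()
        }
        assert depth1 == {"A": 2, "B": 1}
        assert sum(depth1.values()) == path_aba.n_vertices

    def test_prefix_closure_of_start_sets(self):
        # A path realizing a feature also realizes every prefix from the
        # same start, so start sets shrink down the trie.  (Counts need not:
        # one prefix path can extend to many longer paths.)
        g = random_labeled_graph(
            GeneratorConfig(n_vertices=10, m_edges=18, n_labels=2, seed=3)
        )
        index = build_index(Database([g]), lp=4)

        def check(node):
            for child in node.children.values():
                if node.label is not None:  # root is virtual, skip
                    for gid, per_start in child.occurrences.items():
                        parent_start = node.occurrences.get(gid, {})
                        assert set(per_start) <= set(parent_start)
                check(child)

        check(index.root)


class TestPersistence:
    def test_round_trip(self, path_aba):
        index = build_index(Database([path_aba]), lp=2)
        buf = io.StringIO()
        save_index(index, buf)
        loaded = load_index(io.StringIO(buf.getvalue()))
        assert loaded.structurally_equal(index)

    def test_empty_database_round_trip(self):
        index = build_index(Database([]), lp=3)
        buf = io.StringIO()
        save_index(index, buf)
        loaded = load_index(io.StringIO(buf.getvalue()))
        assert loaded.lp == 3
        assert loaded.root.children == {}

    def test_wrong_magic_rejected(self):
        with pytest.raises(IndexFormatError, match="magic"):
            load_index(io.StringIO('{"magic": "something-else"}'))

    def test_truncated_file_rejected(self, path_aba):
        index = build_index(Database([path_aba]), lp=2)
        buf = io.StringIO()
        save_index(index, buf)
        with pytest.raises(IndexFormatError, match="truncated"):
            load_index(io.StringIO(buf.getvalue()[: len(buf.getvalue()) // 2]))

    def test_wrong_version_rejected(self, path_aba):
        index = build_index(Database([path_aba]), lp=2)
        buf = io.StringIO()
        save_index(index, buf)
        tampered = buf.getvalue().replace('"format_version":1', '"format_version":99')
        with pytest.raises(IndexFormatError, match="version"):
            load_index(io.StringIO(tampered))
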
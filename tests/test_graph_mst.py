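"""Maximum spanning tree extraction and tree-topology metrics."""

import itertools

import numpy as np
import pytest

from ebnt import (SpanningTree, betweenness_max, leaf_metrics,
                  maximum_spanning_tree, mst_metrics, tree_hierarchy)

from conftest import random_symmetric_matrix


def tree_from_prufer(seq, n):
    """Decode a Pruefer sequence into the edge list of a labeled tree."""
    import heapq

    degree = [1] * n
    for x in seq:
        degree[x] += 1
    leaves = [i for i in range(n) if degree[i] == 1]
    heapq.heapify(leaves)
    edges = []
    for x in seq:
        leaf = heapq.heappop(leaves)
        edges.append((min(leaf, x), max(leaf, x)))
        degree[x] -= 1
        if degree[x] == 1:
            heapq.heappush(leaves, x)
    u = heapq.heappop(leaves)
    v = heapq.heappop(leaves)
    edges.append((min(u, v), max(u, v)))
    return edges


def all_labeled_trees(n):
    """All n^(n-2) labeled trees on n nodes via Pruefer sequences."""
    for seq in itertools.product(range(n), repeat=n - 2):
        yield tree_from_prufer(list(seq), n)


def star_tree(n):
    return SpanningTree(n, [(0, i) for i in range(1, n)])


def path_tree(n):
    return SpanningTree(n, [(i, i + 1) for i in range(n - 1)])


def random_tree(n, rng):
    seq = rng.integers(0, n, size=n - 2).tolist()
    return SpanningTree(n, tree_from_prufer(seq, n))


class TestMaximumSpanningTree:
    def test_128_nodes_gives_127_edges(self, rng):
        m = random_symmetric_matrix(128, rng)
        tree = maximum_spanning_tree(m)
        assert tree.n_nodes == 128
        assert len(tree.edges) == 127

    def test_three_node_greedy(self):
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = 0.9
        m[0, 2] = m[2, 0] = 0.5
        m[1, 2] = m[2, 1] = 0.2
        tree = maximum_spanning_tree(m)
        assert sorted(tree.edges) == [(0, 1), (0, 2)]
        assert tree.total_weight == pytest.approx(1.4)

    def test_exhaustive_seven_node_oracle(self, rng):
        """Total tree weight equals the maximum over all 7^5 = 16807
        labeled spanning trees enumerated by Pruefer sequences."""
        m = random_symmetric_matrix(7, rng)
        best = max(sum(m[i, j] for i, j in edges)
                   for edges in all_labeled_trees(7))
        tree = maximum_spanning_tree(m)
        assert tree.total_weight == pytest.approx(best, abs=1e-10)

    def test_rank_invariance(self, rng):
        m = random_symmetric_matrix(10, rng)
        a = maximum_spanning_tree(m)
        b = maximum_spanning_tree(np.sqrt(m))
        assert sorted(a.edges) == sorted(b.edges)

    def test_disconnected_input_names_components(self):
        m = np.zeros((4, 4))
        m[0, 1] = m[1, 0] = 0.5
        m[2, 3] = m[3, 2] = 0.5
        with pytest.raises(ValueError, match="components"):
            maximum_spanning_tree(m)

    def test_tie_flagging(self):
        tied = np.ones((4, 4)) - np.eye(4)
        assert maximum_spanning_tree(tied).ties_broken
        distinct = np.zeros((3, 3))
        distinct[0, 1] = distinct[1, 0] = 0.9
        distinct[0, 2] = distinct[2, 0] = 0.5
        distinct[1, 2] = distinct[2, 1] = 0.2
        assert not maximum_spanning_tree(distinct).ties_broken


class TestLeafMetrics:
    def test_star_of_13_has_12_leaves(self):
        ln, lf = leaf_metrics(star_tree(13))
        assert ln == 12
        assert lf == pytest.approx(12 / 13)

    def test_path_of_13_has_2_leaves(self):
        ln, lf = leaf_metrics(path_tree(13))
        assert ln == 2
        assert lf == pytest.approx(2 / 13)

    def test_matches_degree_histogram(self, rng):
        for _ in range(5):
            tree = random_tree(9, rng)
            ln, lf = leaf_metrics(tree)
            assert ln == int((tree.degrees == 1).sum())
            assert 2 <= ln <= 8

    def test_alternative_denominator(self):
        _, lf = leaf_metrics(star_tree(13), fraction_denominator="n_edges")
        assert lf == pytest.approx(1.0)


class TestBetweenness:
    @staticmethod
    def brute_force_bc_max(tree):
        """Path-enumeration oracle: BFS path between every node pair,
        count interior memberships."""
        n = tree.n_nodes
        adj = {i: [] for i in range(n)}
        for i, j in tree.edges:
            adj[i].append(j)
            adj[j].append(i)

        def path(a, b):
            prev = {a: None}
            queue = [a]
            while queue:
                u = queue.pop(0)
                if u == b:
                    break
                for v in adj[u]:
                    if v not in prev:
                        prev[v] = u
                        queue.append(v)
            out = [b]
            while prev[out[-1]] is not None:
                out.append(prev[out[-1]])
            return out

        counts = np.zeros(n)
        for a in range(n):
            for b in range(a + 1, n):
                for interior in path(a, b)[1:-1]:
                    counts[interior] += 1
        return counts.max() / ((n - 1) * (n - 2) / 2)

    def test_star_hub_has_bc_one(self):
        assert betweenness_max(star_tree(9)) == pytest.approx(1.0)

    def test_three_node_path_center(self):
        assert betweenness_max(path_tree(3)) == pytest.approx(1.0)

    def test_matches_path_enumeration_on_random_trees(self, rng):
        for _ in range(5):
            tree = random_tree(8, rng)
            assert betweenness_max(tree) == \
                pytest.approx(self.brute_force_bc_max(tree), abs=1e-12)

    def test_too_small_tree_rejected(self):
        with pytest.raises(ValueError):
            betweenness_max(SpanningTree(2, [(0, 1)]))


class TestTreeHierarchy:
    def test_star_is_exactly_half(self):
        for n in (5, 13, 64):
            assert tree_hierarchy(star_tree(n)) == pytest.approx(0.5)

    def test_path_vanishes_with_length(self):
        # line: LN = 2; TH = 2 / (2 (N-1) bc_max) -> 0 as N grows
        values = [tree_hierarchy(path_tree(n)) for n in (5, 17, 65)]
        assert values[0] > values[1] > values[2]
        assert values[2] < 0.05

    def test_exhaustive_range_on_small_trees(self):
        """Every labeled tree on 4..6 nodes scores in (0, 1]."""
        for n in (4, 5, 6):
            for edges in all_labeled_trees(n):
                th = tree_hierarchy(SpanningTree(n, edges))
                assert 0.0 < th <= 1.0

    def test_intermediate_tree_beats_both_extremes(self):
        # two-hub "double star": high leaf count, split betweenness
        edges = [(0, i) for i in range(2, 7)] + [(1, i) for i in range(7, 12)]
        edges.append((0, 1))
        th = tree_hierarchy(SpanningTree(12, edges))
        assert th > 0.5


class TestTreeInvariants:
    def test_bc_sum_equals_interior_path_length(self, rng):
        """Sum of unnormalized pass-through counts over nodes equals
        the sum over pairs of (path length - 1)."""
        import networkx as nx
        for _ in range(3):
            tree = random_tree(9, rng)
            g = tree.to_networkx()
            bc = nx.betweenness_centrality(g, normalized=False)
            lengths = dict(nx.all_pairs_shortest_path_length(g))
            total = sum(lengths[a][b] - 1
                        for a in range(9) for b in range(a + 1, 9))
            assert sum(bc.values()) == pytest.approx(total)

    def test_mst_metrics_bundle(self, rng):
        m = random_symmetric_matrix(12, rng)
        res = mst_metrics(m)
        assert 2 <= res.leaf_number <= 11
        assert 0 < res.tree_hierarchy <= 1
        assert 0 < res.bc_max <= 1
        assert res.leaf_fraction == pytest.approx(res.leaf_number / 12)
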
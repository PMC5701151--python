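"""Maximum spanning tree extraction and tree-topology metrics.

With similarity weights (PLI), the "minimum connection cost" spanning
tree is the *maximum* weight spanning tree: link cost is the inverse of
connection strength.  The tree is built with Kruskal's algorithm —
edges visited in descending weight, each accepted unless it closes a
loop — yielding an acyclic backbone of N nodes and N-1 strongest
compatible edges.  Because every subject's tree has exactly the same
number of nodes and edges, tree metrics compare groups without any
threshold or normalization step.

Metrics:

* leaf number / leaf fraction — degree-1 nodes; from 2 (a path) up to
  N-1 (a star).  Higher means a more integrated, hub-dominated tree.
* maximum betweenness centrality — the largest fraction of pairwise
  tree paths that pass through any single node; the hub load.
* tree hierarchy TH = LN / (2 m BC_max) with m = N-1 edges — the
  balance between integration (many leaves) and hub overload (large
  BC_max).  A star scores exactly 0.5; a path tends to 0 as N grows;
  intermediate trees can score higher than either extreme.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .connectivity import ConnectivityMatrix
from .graph_weighted import _as_weight_matrix

__all__ = [
    "SpanningTree",
    "MSTMetrics",
    "maximum_spanning_tree",
    "leaf_metrics",
    "betweenness_max",
    "tree_hierarchy",
    "mst_metrics",
]


@dataclass
class SpanningTree:
    """An undirected tree on nodes 0..n_nodes-1 with exactly N-1 edges."""

    n_nodes: int
    edges: list[tuple[int, int]]
    total_weight: float | None = None
    ties_broken: bool = False

    def __post_init__(self) -> None:
        if len(self.edges) != self.n_nodes - 1:
            raise ValueError(
                f"a spanning tree on {self.n_nodes} nodes needs "
                f"{self.n_nodes - 1} edges, got {len(self.edges)}")
        g = self.to_networkx()
        if not nx.is_tree(g) or g.number_of_nodes() != self.n_nodes:
            raise ValueError("edge list does not form a spanning tree")

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.edges)
        return g

    @property
    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg


@dataclass
class MSTMetrics:
    leaf_number: int
    leaf_fraction: float
    bc_max: float
    tree_hierarchy: float
    ties_broken: bool = False
    extra: dict = field(default_factory=dict)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))
        self.rank = [0] * n

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        if self.rank[ra] < self.rank[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        if self.rank[ra] == self.rank[rb]:
            self.rank[ra] += 1
        return True


def maximum_spanning_tree(cm: ConnectivityMatrix | np.ndarray) -> SpanningTree:
    """Kruskal's algorithm on descending edge weights.

    Zero weights are treated as absent edges; a disconnected input
    raises an error naming the components.  Equal weights are ordered
    by ascending node-index pair (deterministic); when the accepted
    edge set depended on such a tie the tree is flagged as non-unique
    via ``ties_broken``.
    """
    w = _as_weight_matrix(cm)
    n = w.shape[0]
    if n < 2:
        raise ValueError("need at least two nodes")
    iu = np.triu_indices(n, k=1)
    weights = w[iu]
    present = weights > 0
    order = np.lexsort((iu[1][present], iu[0][present], -weights[present]))
    ii, jj, ww = iu[0][present][order], iu[1][present][order], \
        weights[present][order]

    uf = _UnionFind(n)
    edges: list[tuple[int, int]] = []
    accepted_w: list[float] = []
    for i, j, weight in zip(ii.tolist(), jj.tolist(), ww.tolist()):
        if uf.union(i, j):
            edges.append((i, j))
            accepted_w.append(weight)
            if len(edges) == n - 1:
                break
    if len(edges) < n - 1:
        comps: dict[int, list[int]] = {}
        for node in range(n):
            comps.setdefault(uf.find(node), []).append(node)
        raise ValueError(
            "graph is disconnected; components: "
            + "; ".join(str(c) for c in comps.values()))

    # the tree is non-unique iff some excluded edge shares its weight
    # with an accepted one (a swap could yield an equal-weight tree)
    accepted_set = set(zip((e[0] for e in edges), (e[1] for e in edges)))
    excluded_w = {float(weight) for i, j, weight in
                  zip(ii.tolist(), jj.tolist(), ww.tolist())
                  if (i, j) not in accepted_set}
    ties = bool(excluded_w & set(map(float, accepted_w)))
    return SpanningTree(n_nodes=n, edges=edges,
                        total_weight=float(sum(accepted_w)),
                        ties_broken=ties)


def leaf_metrics(tree: SpanningTree,
                 fraction_denominator: str = "n_nodes"
                 ) -> tuple[int, float]:
    """Leaf count and leaf fraction.

    ``fraction_denominator`` is ``"n_nodes"`` (literal fraction of leaf
    nodes, LN/N, the default) or ``"n_edges"`` (LN/(N-1)).
    """
    leaf_number = int((tree.degrees == 1).sum())
    if fraction_denominator == "n_nodes":
        denom = tree.n_nodes
    elif fraction_denominator == "n_edges":
        denom = tree.n_nodes - 1
    else:
        raise ValueError("fraction_denominator must be 'n_nodes' or 'n_edges'")
    return leaf_number, leaf_number / denom


def betweenness_max(tree: SpanningTree) -> float:
    """Maximum normalized betweenness centrality over tree nodes.

    Each node's BC is the fraction of the (N-1)(N-2)/2 node pairs
    (excluding itself) whose unique tree path passes through it; the
    star hub scores exactly 1.
    """
    if tree.n_nodes < 3:
        raise ValueError("betweenness needs at least three nodes")
    bc = nx.betweenness_centrality(tree.to_networkx(), normalized=True)
    return float(max(bc.values()))


def tree_hierarchy(tree: SpanningTree) -> float:
    """TH = LN / (2 m BC_max), m = N-1 edges; in (0, 1]."""
    if tree.n_nodes < 3:
        raise ValueError("tree hierarchy needs at least three nodes")
    leaf_number, _ = leaf_metrics(tree)
    bc_max = betweenness_max(tree)
    m = tree.n_nodes - 1
    return leaf_number / (2.0 * m * bc_max)


def mst_metrics(cm: ConnectivityMatrix | np.ndarray,
                fraction_denominator: str = "n_nodes") -> MSTMetrics:
    """Maximum spanning tree of the connectivity matrix plus its metrics."""
    tree = maximum_spanning_tree(cm)
    leaf_number, leaf_fraction = leaf_metrics(tree, fraction_denominator)
    bc_max = betweenness_max(tree)
    m = tree.n_nodes - 1
    return MSTMetrics(
        leaf_number=leaf_number,
        leaf_fraction=leaf_fraction,
        bc_max=bc_max,
        tree_hierarchy=leaf_number / (2.0 * m * bc_max),
        ties_broken=tree.ties_broken,
        extra={"total_weight": tree.total_weight},
    )
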
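"""Maximum spanning tree extraction and edge-disjoint rank decomposition.

The maximum spanning tree (MST) keeps, for the whole graph, the strongest
links that do not form cycles: greedy descent over edges sorted by
(descending weight, ascending node pair) with union-find cycle detection
(Kruskal).  The lexicographic tie-break makes equal-weight graphs yield one
canonical tree.

The rank-n MST is the MST of the graph after deleting the edges of the
previous n-1 MSTs; the ranked trees are pairwise edge-disjoint and their
total weights are non-increasing in rank.  If the working graph disconnects
before the requested rank the operation fails loudly with the achieved rank
(downstream allometry is defined on trees only, so no forest fallback).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._disjoint import DisjointSet
from .errors import DataError, DisconnectedGraphError, RankExhaustedError
from .networks import WeightedBrainGraph


@dataclass
class SpanningTree:
    """A spanning tree as a weighted edge list over nodes 0..n-1."""

    edges: list[tuple[int, int, float]]
    n_nodes: int
    rank: int = 1
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        if len(self.edges) != self.n_nodes - 1:
            raise DataError(
                f"a spanning tree on {self.n_nodes} nodes needs "
                f"{self.n_nodes - 1} edges, got {len(self.edges)}"
            )

    @property
    def total_weight(self) -> float:
        return float(sum(w for _, _, w in self.edges))

    def adjacency(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for u, v, _ in self.edges:
            adj[u].append(v)
            adj[v].append(u)
        return adj

    def edge_set(self) -> set[tuple[int, int]]:
        return {(min(u, v), max(u, v)) for u, v, _ in self.edges}

    def validate(self) -> None:
        """Assert tree-ness: n-1 edges, acyclic, connected."""
        ds = DisjointSet(self.n_nodes)
        for u, v, _ in self.edges:
            if not ds.union(u, v):
                raise DataError(f"edge ({u}, {v}) closes a cycle")
        if ds.n_components != 1:
            raise DataError("edge set does not span all nodes")


@dataclass
class RankedTreeSet:
    """Edge-disjoint spanning trees of one graph, ordered by rank."""

    trees: list[SpanningTree]

    def __post_init__(self):
        seen: set[tuple[int, int]] = set()
        for t in self.trees:
            es = t.edge_set()
            if es & seen:
                raise DataError("ranked trees are not edge-disjoint")
            seen |= es

    def __iter__(self):
        return iter(self.trees)

    def __len__(self):
        return len(self.trees)

    def __getitem__(self, i):
        return self.trees[i]


def _sorted_edges(graph: WeightedBrainGraph):
    """Edges sorted by (descending weight, ascending node pair)."""
    w_mat = graph.weights
    iu, jv = np.triu_indices(graph.n_nodes, 1)
    w = w_mat[iu, jv]
    present = w > 0
    ei, ej, w = iu[present], jv[present], w[present]
    order = np.lexsort((ej, ei, -w))
    return ei[order].tolist(), ej[order].tolist(), w[order].tolist()


def _check_connected(n: int, ei, ej) -> None:
    ds = DisjointSet(n)
    for u, v in zip(ei, ej):
        ds.union(u, v)
    if ds.n_components != 1:
        comps = ds.components()
        raise DisconnectedGraphError(
            f"graph is disconnected: {len(comps)} components with sizes "
            f"{sorted(len(c) for c in comps)}",
            components=comps,
        )


def _kruskal_max(n, ei, ej, w, skip: set | None, rank: int, labels) -> SpanningTree | None:
    ds = DisjointSet(n)
    edges: list[tuple[int, int, float]] = []
    for u, v, weight in zip(ei, ej, w):
        if skip is not None and (u, v) in skip:
            continue
        if ds.union(u, v):
            edges.append((u, v, weight))
            if len(edges) == n - 1:
                return SpanningTree(edges=edges, n_nodes=n, rank=rank,
                                    node_labels=list(labels))
    return None


def maximum_spanning_tree(graph: WeightedBrainGraph) -> SpanningTree:
    """Spanning tree of maximal total weight (deterministic under ties)."""
    n = graph.n_nodes
    if n < 2:
        raise DataError("maximum spanning tree needs at least 2 nodes")
    ei, ej, w = _sorted_edges(graph)
    _check_connected(n, ei, ej)
    tree = _kruskal_max(n, ei, ej, w, None, 1, graph.node_labels)
    assert tree is not None  # connected input guarantees a spanning tree
    return tree


def ranked_msts(graph: WeightedBrainGraph, n_ranks: int = 4) -> RankedTreeSet:
    """First ``n_ranks`` edge-disjoint maximum spanning trees.

    Rank 1 is the MST of the graph; rank k is the MST after deleting the
    edges of ranks 1..k-1.  Raises :class:`RankExhaustedError` (with the
    achieved rank) if the residual graph disconnects early.  For complete
    graphs this cannot happen while ``n_ranks <= floor(n / 2)``.
    """
    if n_ranks < 1:
        raise DataError("n_ranks must be >= 1")
    n = graph.n_nodes
    ei, ej, w = _sorted_edges(graph)
    _check_connected(n, ei, ej)
    used: set[tuple[int, int]] = set()
    trees: list[SpanningTree] = []
    for rank in range(1, n_ranks + 1):
        tree = _kruskal_max(n, ei, ej, w, used if used else None, rank, graph.node_labels)
        if tree is None:
            raise RankExhaustedError(
                f"graph disconnected at rank {rank}: only {rank - 1} "
                f"edge-disjoint spanning trees exist",
                achieved_rank=rank - 1,
            )
        used |= tree.edge_set()
        trees.append(tree)
    return RankedTreeSet(trees=trees)


def tree_to_edge_table(tree: SpanningTree):
    """Edge list as a pandas DataFrame (for TSV export)."""
    import pandas as pd

    labels = tree.node_labels or [str(i) for i in range(tree.n_nodes)]
    rows = [
        {"rank": tree.rank, "node_a": labels[u], "node_b": labels[v], "weight": w}
        for u, v, w in tree.edges
    ]
    return pd.DataFrame(rows, columns=["rank", "node_a", "node_b", "weight"])
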
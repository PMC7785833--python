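"""Maximum-connectivity spanning tree extraction (Kruskal with DFS cycle test).

The weighted graph is the complete graph over the channels with tPLV values
as edge weights; no pre-thresholding is applied.  Kruskal's algorithm sorted
for *maximum* total weight yields the maximum-connectivity spanning tree,
an unweighted, acyclic, connected graph on all N nodes with N - 1 edges.
Because the algorithm depends only on the ordering of the weights, the tree
is invariant under any strictly increasing transform of the weights and is
unaffected by the sign of z-normalized connectivity values.

Tie-breaking (relevant only for synthetic edge cases; continuous connectivity
values tie with probability zero): edges are sorted by descending weight,
ties broken lexicographically by (smaller node index, larger node index).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .connectivity import ConnectivityMatrix

Edge = tuple[int, int]


def _normalize_edge(edge) -> Edge:
    a, b = int(edge[0]), int(edge[1])
    if a == b:
        raise ValueError(f"self-loop edge ({a}, {b})")
    return (a, b) if a < b else (b, a)


@dataclass
class TreeGraph:
    """An unweighted spanning tree over the channel set.

    ``edges`` are unordered node pairs stored as sorted tuples; the graph
    must be connected and acyclic with exactly ``n_nodes - 1`` edges.
    """

    n_nodes: int
    edges: tuple[Edge, ...]
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.edges = tuple(sorted(_normalize_edge(e) for e in self.edges))
        if not self.channel_labels:
            width = len(str(self.n_nodes))
            self.channel_labels = [f"CH{i + 1:0{width}d}" for i in range(self.n_nodes)]
        if len(self.channel_labels) != self.n_nodes:
            raise ValueError("channel_labels length must equal n_nodes")
        if len(set(self.edges)) != len(self.edges):
            raise ValueError("duplicate edges in tree")
        if any(a < 0 or b >= self.n_nodes for a, b in self.edges):
            raise ValueError("edge endpoint out of range")
        if len(self.edges) != self.n_nodes - 1:
            raise ValueError(
                f"a spanning tree on {self.n_nodes} nodes needs "
                f"{self.n_nodes - 1} edges, got {len(self.edges)}"
            )
        if not nx.is_connected(self.to_networkx()):
            raise ValueError("tree is not connected")
        # n-1 edges + connected => acyclic; no separate check needed.

    @property
    def adjacency(self) -> np.ndarray:
        """Binary symmetric adjacency matrix with zero diagonal."""
        adj = np.zeros((self.n_nodes, self.n_nodes), dtype=int)
        for a, b in self.edges:
            adj[a, b] = adj[b, a] = 1
        return adj

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.edges)
        return g

    def edge_labels(self) -> list[tuple[str, str]]:
        return [(self.channel_labels[a], self.channel_labels[b]) for a, b in self.edges]

    def relabel(self, permutation: np.ndarray) -> "TreeGraph":
        """Return the tree with node i renamed to permutation[i]."""
        perm = np.asarray(permutation, dtype=int)
        new_labels = [""] * self.n_nodes
        for i, p in enumerate(perm):
            new_labels[p] = self.channel_labels[i]
        return TreeGraph(
            n_nodes=self.n_nodes,
            edges=tuple((perm[a], perm[b]) for a, b in self.edges),
            channel_labels=new_labels,
        )


def has_cycle_after_adding(tree_so_far, candidate, n_nodes: int | None = None) -> bool:
    """Would adding ``candidate`` to an acyclic edge set close a loop?

    Implemented, for fidelity with the construction it supports, as a
    depth-first search over the graph including the candidate edge: a cycle
    exists iff some visited node sees an already-visited neighbour that is
    not its DFS parent.  Equivalent to asking whether the candidate's
    endpoints are already connected.
    """
    cand = _normalize_edge(candidate)
    edges = [_normalize_edge(e) for e in tree_so_far]
    nodes = {n for e in edges for n in e} | set(cand)
    if n_nodes is not None and (cand[1] >= n_nodes or cand[0] < 0):
        raise ValueError(f"candidate endpoint out of range: {cand}")
    adjacency: dict[int, list[int]] = {n: [] for n in nodes}
    for a, b in edges + [cand]:
        adjacency[a].append(b)
        adjacency[b].append(a)

    visited: set[int] = set()
    for root in nodes:
        if root in visited:
            continue
        stack = [(root, -1)]
        while stack:
            node, parent = stack.pop()
            if node in visited:
                return True  # reached an already-visited node again
            visited.add(node)
            for neighbour in adjacency[node]:
                if neighbour == parent:
                    continue
                if neighbour in visited:
                    return True
                stack.append((neighbour, node))
    return False


def kruskal_max_tree(conn: ConnectivityMatrix) -> TreeGraph:
    """Maximum-weight spanning tree of a connectivity matrix via Kruskal.

    Edges of the complete graph are sorted by descending weight (ties broken
    lexicographically) and greedily added unless they would close a cycle,
    until N - 1 edges are placed.
    """
    w = conn.matrix
    n = conn.n_nodes
    if n < 2:
        raise ValueError("need at least 2 nodes to span a tree")
    iu = np.triu_indices(n, k=1)
    weights = w[iu]
    if not np.all(np.isfinite(weights)):
        raise ValueError("connectivity weights must be finite")
    order = sorted(
        range(len(weights)), key=lambda i: (-weights[i], iu[0][i], iu[1][i])
    )
    chosen: list[Edge] = []
    for i in order:
        candidate = (int(iu[0][i]), int(iu[1][i]))
        if not has_cycle_after_adding(chosen, candidate, n_nodes=n):
            chosen.append(candidate)
            if len(chosen) == n - 1:
                break
    return TreeGraph(n_nodes=n, edges=tuple(chosen),
                     channel_labels=list(conn.channel_labels))


def group_tree(matrices: list[ConnectivityMatrix]) -> TreeGraph:
    """Spanning tree of the element-wise mean connectivity across subjects."""
    if not matrices:
        raise ValueError("need at least one connectivity matrix")
    labels = matrices[0].channel_labels
    for m in matrices[1:]:
        if m.channel_labels != labels:
            raise ValueError("channel labels differ across subjects")
    mean = np.mean([m.matrix for m in matrices], axis=0)
    avg = ConnectivityMatrix(
        matrix=mean, channel_labels=list(labels),
        m_samples=matrices[0].m_samples, n_trials=matrices[0].n_trials,
    )
    return kruskal_max_tree(avg)


def star_edges(n_nodes: int, hub: int = 0) -> tuple[Edge, ...]:
    """Star topology: one hub connected to every other node."""
    if not 0 <= hub < n_nodes:
        raise ValueError("hub index out of range")
    return tuple((min(hub, i), max(hub, i)) for i in range(n_nodes) if i != hub)


def line_edges(n_nodes: int) -> tuple[Edge, ...]:
    """Line (path) topology: nodes chained 0-1-2-...-(n-1)."""
    return tuple((i, i + 1) for i in range(n_nodes - 1))


def random_tree_edges(n_nodes: int, rng: np.random.Generator) -> tuple[Edge, ...]:
    """A uniformly random labelled tree, decoded from a Pruefer sequence."""
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    if n_nodes == 2:
        return ((0, 1),)
    seq = rng.integers(0, n_nodes, size=n_nodes - 2)
    degree = np.ones(n_nodes, dtype=int)
    for s in seq:
        degree[s] += 1
    edges: list[Edge] = []
    leaves = sorted(i for i in range(n_nodes) if degree[i] == 1)
    heapq.heapify(leaves)
    for s in seq:
        leaf = heapq.heappop(leaves)
        edges.append(_normalize_edge((leaf, int(s))))
        degree[s] -= 1
        if degree[s] == 1:
            heapq.heappush(leaves, int(s))
    u = heapq.heappop(leaves)
    v = heapq.heappop(leaves)
    edges.append(_normalize_edge((u, v)))
    return tuple(edges)
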
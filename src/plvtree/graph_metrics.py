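"""Nodal and global topology metrics for spanning trees.

Nodal metrics: degree k, betweenness centrality BC (fraction of shortest
paths between other node pairs passing through the node, normalized so a
star hub scores 1 and every leaf scores 0), and eccentricity (longest hop
distance to any other node).

Global metrics: leaf count L and leaf fraction L_f = L/(N-1); maximum degree
k_max; maximum betweenness BC_max; global eccentricity (by default the range
max - min of the nodal eccentricities); degree divergence
kappa = sum(k^2)/sum(k); diameter D = (longest shortest path)/(N-1); and
tree hierarchy T_H = L / (2 (N-1) BC_max), which is 0.5 for a star and tends
to 0 for a long line.  The subject's global PLV can be carried along for
reporting.

Values are kept at full precision internally; rounding to two decimals is a
reporting-layer concern only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import networkx as nx
import numpy as np
import pandas as pd

from .mst import TreeGraph

#: Metrics compared between groups, in reporting order.
GLOBAL_METRIC_NAMES = (
    "gplv", "k_max", "leaf_fraction", "diameter", "bc_max",
    "eccentricity", "kappa", "tree_hierarchy",
)


@dataclass
class NodalMetrics:
    """Per-node degree, betweenness centrality and eccentricity."""

    degree: np.ndarray
    betweenness: np.ndarray
    eccentricity: np.ndarray
    channel_labels: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "channel": self.channel_labels,
                "degree": self.degree,
                "betweenness": self.betweenness,
                "eccentricity": self.eccentricity,
            }
        )


@dataclass
class GlobalMetrics:
    """Whole-tree summary metrics (see module docstring for definitions)."""

    leaf_count: int
    leaf_fraction: float
    k_max: int
    bc_max: float
    eccentricity: float
    kappa: float
    diameter: float
    tree_hierarchy: float
    gplv: float = float("nan")
    #: max nodal eccentricity, kept alongside the default range variant
    eccentricity_max: int = 0

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class OccurrenceTable:
    """Hub and edge occurrence fractions across the individual trees of a group.

    ``hub_occurrence[i]`` is the share of subjects in which channel i is a
    hub (degree > 1); ``edge_occurrence[i, j]`` the share of subjects whose
    tree contains edge {i, j}.  ``frequent_edges`` lists the edges above the
    display threshold (default: present in more than 25% of subjects).
    """

    hub_occurrence: np.ndarray
    edge_occurrence: np.ndarray
    n_subjects: int
    channel_labels: list[str]
    threshold: float = 0.25
    frequent_edges: list[tuple[int, int]] = field(default_factory=list)

    def hub_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"channel": self.channel_labels, "hub_occurrence": self.hub_occurrence}
        )

    def edge_frame(self) -> pd.DataFrame:
        rows = []
        n = len(self.channel_labels)
        for i in range(n):
            for j in range(i + 1, n):
                if self.edge_occurrence[i, j] > 0:
                    rows.append(
                        {
                            "channel_a": self.channel_labels[i],
                            "channel_b": self.channel_labels[j],
                            "occurrence": self.edge_occurrence[i, j],
                            "above_threshold": self.edge_occurrence[i, j]
                            > self.threshold,
                        }
                    )
        return pd.DataFrame(rows)


@dataclass
class SimilarityResult:
    """Edge overlap between an individual tree and a reference tree."""

    shared_edges: int
    overlap_fraction: float
    n_nodes: int

    @property
    def overlap_percent(self) -> float:
        return 100.0 * self.overlap_fraction


def nodal_metrics(tree: TreeGraph) -> NodalMetrics:
    """Degree, betweenness centrality and eccentricity for every node.

    In a tree every node pair has exactly one shortest path, so betweenness
    reduces to counting, per node r, the pairs {p, q} (p, q != r) whose
    unique path passes through r, divided by the number of such pairs
    (N-1)(N-2)/2.  This makes BC(hub) = 1 in a star and BC(leaf) = 0 always.
    """
    g = tree.to_networkx()
    n = tree.n_nodes
    degree = tree.degrees()
    if n >= 3:
        bc_map = nx.betweenness_centrality(g, normalized=True)
        betweenness = np.array([bc_map[i] for i in range(n)])
    else:
        betweenness = np.zeros(n)
    ecc_map = nx.eccentricity(g)
    eccentricity = np.array([ecc_map[i] for i in range(n)], dtype=int)
    return NodalMetrics(
        degree=degree, betweenness=betweenness, eccentricity=eccentricity,
        channel_labels=list(tree.channel_labels),
    )


def global_metrics(
    tree: TreeGraph,
    gplv: float = float("nan"),
    nodal: NodalMetrics | None = None,
    ecc_variant: str = "range",
) -> GlobalMetrics:
    """Whole-tree topology summary.

    Parameters
    ----------
    tree : TreeGraph
    gplv : float, optional
        Subject-level global PLV to carry into the report.
    nodal : NodalMetrics, optional
        Precomputed nodal metrics (recomputed if omitted).
    ecc_variant : {"range", "max"}
        Global eccentricity as the range (max - min) of nodal eccentricities
        (the default) or as the maximum nodal eccentricity (equal to the
        unnormalized diameter).
    """
    if tree.n_nodes < 3:
        raise ValueError("global metrics need >= 3 nodes (BC_max is 0 for N = 2)")
    nm = nodal if nodal is not None else nodal_metrics(tree)
    n = tree.n_nodes
    degree = nm.degree
    leaf_count = int(np.sum(degree == 1))
    k_max = int(degree.max())
    bc_max = float(nm.betweenness.max())
    ecc_max = int(nm.eccentricity.max())
    if ecc_variant == "range":
        ecc_global = float(ecc_max - nm.eccentricity.min())
    elif ecc_variant == "max":
        ecc_global = float(ecc_max)
    else:
        raise ValueError("ecc_variant must be 'range' or 'max'")
    kappa = float(np.sum(degree**2) / np.sum(degree))
    diameter = ecc_max / (n - 1)
    tree_hierarchy = leaf_count / (2.0 * (n - 1) * bc_max)
    return GlobalMetrics(
        leaf_count=leaf_count,
        leaf_fraction=leaf_count / (n - 1),
        k_max=k_max,
        bc_max=bc_max,
        eccentricity=ecc_global,
        kappa=kappa,
        diameter=diameter,
        tree_hierarchy=tree_hierarchy,
        gplv=gplv,
        eccentricity_max=ecc_max,
    )


def occurrence(trees: list[TreeGraph], threshold: float = 0.25) -> OccurrenceTable:
    """Hub and edge occurrence fractions over the individual trees of a group."""
    if not trees:
        raise ValueError("need at least one tree")
    labels = trees[0].channel_labels
    n = trees[0].n_nodes
    for t in trees[1:]:
        if t.channel_labels != labels:
            raise ValueError("channel labels differ across trees")
    hub_counts = np.zeros(n)
    edge_counts = np.zeros((n, n))
    for t in trees:
        hub_counts += t.degrees() > 1
        edge_counts += t.adjacency
    n_subj = len(trees)
    edge_occ = edge_counts / n_subj
    frequent = [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if edge_occ[i, j] > threshold
    ]
    return OccurrenceTable(
        hub_occurrence=hub_counts / n_subj,
        edge_occurrence=edge_occ,
        n_subjects=n_subj,
        channel_labels=list(labels),
        threshold=threshold,
        frequent_edges=frequent,
    )


def overlap(tree: TreeGraph, reference: TreeGraph) -> SimilarityResult:
    """Fraction of edges an individual tree shares with a reference tree."""
    if tree.n_nodes != reference.n_nodes:
        raise ValueError("trees have different node counts")
    shared = len(set(tree.edges) & set(reference.edges))
    return SimilarityResult(
        shared_edges=shared,
        overlap_fraction=shared / (tree.n_nodes - 1),
        n_nodes=tree.n_nodes,
    )
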
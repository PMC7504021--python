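"""Topological characterization of signaling networks.

Implements the standard panel used to describe literature-curated molecular
networks: per-node and network clustering coefficient, network diameter and
characteristic path length, average neighbor count, betweenness and
closeness centrality, and the degree-vs-clustering regression used to argue
for scale-free (Barabási–Albert-like) structure.

Conventions
-----------
* Path metrics run in directed mode by default (signal flow has a
  direction); ordered node pairs with no connecting path are excluded from
  both the diameter and the average, never counted as infinite.
* The clustering coefficient C_I = 2 n_I / (k_I (k_I − 1)) is the undirected
  form and is always computed on the undirected projection; nodes with fewer
  than two neighbors score 0.
* Betweenness is normalized per connected component: raw transit counts are
  divided by the number of node pairs excluding the node itself —
  (N−1)(N−2)/2 unordered pairs for undirected graphs, (N−1)(N−2) ordered
  pairs for directed graphs, with N the size of the node's (weak) component
  — so every value lies in [0, 1].
* Closeness of a node is the reciprocal of its mean shortest-path distance
  to the nodes it can reach; nodes that reach nothing (isolated nodes, pure
  sinks in directed mode) score 0.  This reachable-set convention keeps
  values in [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import networkx as nx
import numpy as np
import pandas as pd

from .network_core import as_digraph, undirected_projection, weakly_connected_components

__all__ = [
    "TopologyReport",
    "CentralityTable",
    "clustering_coefficient",
    "network_clustering_coefficient",
    "shortest_path_panel",
    "avg_neighbors",
    "betweenness",
    "closeness",
    "degree_vs_clustering_r2",
    "centrality_table",
    "compute_topology_report",
]


@dataclass
class TopologyReport:
    """The full topological parameter panel for one network."""

    n_components: int
    n_nodes: int
    n_edges: int
    clustering_coefficient: float
    diameter: int | None
    characteristic_path_length: float | None
    avg_neighbors: float
    degree_vs_clustering_r2: float | None

    def as_dict(self) -> dict:
        return {
            "n_components": self.n_components,
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "clustering_coefficient": self.clustering_coefficient,
            "diameter": self.diameter,
            "characteristic_path_length": self.characteristic_path_length,
            "avg_neighbors": self.avg_neighbors,
            "degree_vs_clustering_r2": self.degree_vs_clustering_r2,
        }


@dataclass
class CentralityTable:
    """Per-node centrality panel: betweenness, closeness, degrees."""

    frame: pd.DataFrame

    def to_tsv(self, stream) -> None:
        self.frame.to_csv(stream, sep="\t", index_label="node")


def clustering_coefficient(network, node) -> float:
    """C_I = 2 n_I / (k_I (k_I − 1)) on the undirected projection.

    n_I is the number of edges among the node's k_I neighbors; nodes with
    fewer than two neighbors return 0.
    """
    proj = undirected_projection(network)
    if node not in proj:
        raise KeyError(f"unknown node: {node!r}")
    return nx.clustering(proj, node)


def network_clustering_coefficient(network) -> float:
    """Unweighted mean of per-node clustering coefficients over all nodes."""
    proj = undirected_projection(network)
    if proj.number_of_nodes() == 0:
        raise ValueError("network is empty")
    values = nx.clustering(proj)
    return float(sum(values.values()) / len(values))


def shortest_path_panel(
    network, direction: Literal["directed", "undirected"] = "directed"
) -> tuple[int | None, float | None]:
    """(diameter, characteristic path length) over connected ordered pairs.

    Distances are hop counts over ordered pairs (u, v), u ≠ v, for which a
    path exists; unreachable pairs are excluded.  If no pair is connected at
    all, both values are ``None``.
    """
    graph = as_digraph(network)
    if graph.number_of_nodes() < 2:
        raise ValueError("shortest-path panel needs at least 2 nodes")
    if direction == "undirected":
        graph = undirected_projection(graph)
    elif direction != "directed":
        raise ValueError(f"direction must be 'directed' or 'undirected', got {direction!r}")
    distances = []
    for _, dists in nx.all_pairs_shortest_path_length(graph):
        distances.extend(d for d in dists.values() if d > 0)
    if not distances:
        return None, None
    return int(max(distances)), float(sum(distances) / len(distances))


def avg_neighbors(network) -> float:
    """Mean number of distinct neighbors per node (undirected projection)."""
    proj = undirected_projection(network)
    n = proj.number_of_nodes()
    if n == 0:
        raise ValueError("network is empty")
    return float(sum(dict(proj.degree()).values()) / n)


def betweenness(network) -> dict:
    """Betweenness centrality C_b(n) = Σ_{s≠n≠t} σ_st(n)/σ_st, normalized.

    σ_st is the number of shortest s→t paths and σ_st(n) the number passing
    through n (endpoints excluded).  Raw scores are divided by the number of
    node pairs excluding n within n's connected component, so every value is
    in [0, 1]; nodes in components of fewer than 3 nodes score 0.  Raises on
    multigraph input: shortest-path counting is only defined on simple
    graphs.
    """
    graph = as_digraph(network)
    if graph.is_multigraph():
        raise ValueError("betweenness requires a simple graph (no multiple edges)")
    raw = nx.betweenness_centrality(graph, normalized=False)
    result: dict = {}
    for component in weakly_connected_components(graph):
        n = len(component)
        if graph.is_directed():
            denom = (n - 1) * (n - 2)  # ordered transit pairs
        else:
            denom = (n - 1) * (n - 2) / 2  # unordered transit pairs
        for node in component:
            result[node] = float(raw[node] / denom) if denom > 0 else 0.0
    return result


def closeness(network, distance_direction: Literal["out", "in"] = "out") -> dict:
    """Closeness centrality C_c(n) = 1 / mean(L(n, m)) over reachable m.

    For directed graphs, ``distance_direction="out"`` measures how fast
    information spreads *from* the node (distances along edge direction);
    ``"in"`` measures distances toward it.  Nodes reaching no other node
    (isolated nodes in particular) score 0.
    """
    graph = as_digraph(network)
    if graph.is_directed() and distance_direction == "in":
        graph = graph.reverse(copy=False)
    result: dict = {}
    for node in graph.nodes:
        dists = nx.single_source_shortest_path_length(graph, node)
        reach = [d for d in dists.values() if d > 0]
        result[node] = float(len(reach) / sum(reach)) if reach else 0.0
    return result


def degree_vs_clustering_r2(network) -> float | None:
    """R² of the least-squares line of clustering coefficient on total degree.

    A near-zero value together with the presence of hubs is the classical
    signature of Barabási–Albert scale-free structure.  Returns ``None``
    when the degrees have zero variance (no line can be fit); when the
    clustering values have zero variance the flat line explains nothing and
    the value is 0 by convention.
    """
    graph = as_digraph(network)
    if graph.number_of_nodes() < 3:
        raise ValueError("regression needs at least 3 nodes")
    proj = undirected_projection(graph)
    clustering = nx.clustering(proj)
    nodes = list(graph.nodes)
    x = np.array([graph.degree(v) for v in nodes], dtype=float)
    y = np.array([clustering[v] for v in nodes], dtype=float)
    if np.ptp(x) == 0:
        return None
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return 0.0
    slope, intercept = np.polyfit(x, y, 1)
    ss_res = float(np.sum((y - (slope * x + intercept)) ** 2))
    return float(1.0 - ss_res / ss_tot)


def centrality_table(
    network, distance_direction: Literal["out", "in"] = "out"
) -> CentralityTable:
    """Assemble the per-node centrality panel as a sorted table."""
    graph = as_digraph(network)
    btw = betweenness(graph)
    cls = closeness(graph, distance_direction=distance_direction)
    rows = {}
    for node in sorted(graph.nodes, key=str):
        if graph.is_directed():
            deg_in, deg_out = graph.in_degree(node), graph.out_degree(node)
        else:
            deg_in = deg_out = graph.degree(node)
        rows[node] = {
            "betweenness": btw[node],
            "closeness": cls[node],
            "degree_in": deg_in,
            "degree_out": deg_out,
            "degree_total": graph.degree(node),
        }
    return CentralityTable(frame=pd.DataFrame.from_dict(rows, orient="index"))


def compute_topology_report(
    network, direction: Literal["directed", "undirected"] = "directed"
) -> TopologyReport:
    """Compute the full topology panel for one network."""
    graph = as_digraph(network)
    n_nodes = graph.number_of_nodes()
    n_edges = graph.number_of_edges()
    diameter, cpl = (None, None)
    if n_nodes >= 2:
        diameter, cpl = shortest_path_panel(graph, direction=direction)
    try:
        r2 = degree_vs_clustering_r2(graph)
    except ValueError:
        r2 = None
    return TopologyReport(
        n_components=len(weakly_connected_components(graph)),
        n_nodes=n_nodes,
        n_edges=n_edges,
        clustering_coefficient=network_clustering_coefficient(graph),
        diameter=diameter,
        characteristic_path_length=cpl,
        avg_neighbors=avg_neighbors(graph),
        degree_vs_clustering_r2=r2,
    )
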
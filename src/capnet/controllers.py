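"""Identification of network controllers: hubs, bottlenecks, and layers.

Hubs are the hyper-connected nodes: those whose degree strictly exceeds the
mean node degree plus one standard deviation (ND > μ + σ).  Bottlenecks
control information flux: the bottleneck score BN(v) counts, over one
shortest-path tree T_s per root s, the roots for which more than a quarter
of the tree's root-to-node paths pass through v.  The hierarchical layer
assignment orders nodes by signal flow: strongly connected components are
condensed, components with no incoming edges form layer 0 (the pathway
inputs), and every other component sits at its longest-path depth from
layer 0 — separating input, information-processing, and effector levels of
a signaling cascade.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Literal, Mapping

import networkx as nx
import numpy as np

from .network_core import as_digraph, undirected_projection

__all__ = [
    "HubReport",
    "BottleneckTable",
    "LayerAssignment",
    "identify_hubs",
    "bottleneck_scores",
    "hierarchical_layers",
    "shortest_path_tree",
]


@dataclass(frozen=True)
class HubReport:
    """Hub detection result: threshold statistics and the flagged nodes."""

    mu: float
    sigma: float
    threshold: float
    hubs: Mapping[str, int]  # node -> degree, for nodes with degree > threshold


@dataclass(frozen=True)
class BottleneckTable:
    """Per-node bottleneck scores BN(v) (non-negative integers)."""

    scores: Mapping[str, int]

    def top(self, n: int = 3) -> list[tuple[str, int]]:
        return sorted(self.scores.items(), key=lambda kv: (-kv[1], str(kv[0])))[:n]


@dataclass(frozen=True)
class LayerAssignment:
    """Node → hierarchical layer index (0 = pathway inputs)."""

    layers: Mapping[str, int]


def identify_hubs(
    network,
    degree_mode: Literal["total", "in", "out"] = "total",
    sigma_kind: Literal["population", "sample"] = "population",
) -> HubReport:
    """Flag nodes whose degree strictly exceeds μ + σ.

    μ and σ are computed over the degrees of *all* nodes in the chosen mode.
    The population standard deviation is the default: the node set is the
    entire network, not a sample from one.  A regular graph (σ = 0, all
    degrees equal to μ) has no hubs under the strict inequality.
    """
    graph = as_digraph(network)
    if graph.number_of_nodes() == 0:
        raise ValueError("network is empty")
    if not graph.is_directed() or degree_mode == "total":
        degrees = dict(graph.degree())
    elif degree_mode == "in":
        degrees = dict(graph.in_degree())
    elif degree_mode == "out":
        degrees = dict(graph.out_degree())
    else:
        raise ValueError(f"degree_mode must be 'total', 'in' or 'out', got {degree_mode!r}")
    values = np.array(list(degrees.values()), dtype=float)
    mu = float(values.mean())
    ddof = 0 if sigma_kind == "population" else 1
    if sigma_kind not in ("population", "sample"):
        raise ValueError(f"sigma_kind must be 'population' or 'sample', got {sigma_kind!r}")
    sigma = float(values.std(ddof=ddof)) if values.size > ddof else 0.0
    threshold = mu + sigma
    hubs = {v: int(d) for v, d in degrees.items() if d > threshold}
    return HubReport(mu=mu, sigma=sigma, threshold=threshold, hubs=hubs)


def shortest_path_tree(graph, root) -> dict:
    """Deterministic BFS shortest-path tree rooted at ``root``.

    Returns a parent map (root → None).  Ties between equal-distance
    predecessors break to the lexicographically smallest label, so the tree
    is identical across runs and platforms.  Directed graphs are traversed
    along edge direction.
    """
    if root not in graph:
        raise KeyError(f"unknown root: {root!r}")
    dist = {root: 0}
    parent = {root: None}
    queue = deque([root])
    while queue:
        u = queue.popleft()
        for v in sorted(graph.successors(u) if graph.is_directed() else graph.neighbors(u), key=str):
            if v not in dist:
                dist[v] = dist[u] + 1
                parent[v] = u
                queue.append(v)
            elif dist[v] == dist[u] + 1 and str(u) < str(parent[v]):
                parent[v] = u
    return parent


def bottleneck_scores(network) -> BottleneckTable:
    """BN(v) = Σ_s p_s(v) over one shortest-path tree per root s.

    Within the tree T_s rooted at s, a root-to-node path "meets" a vertex v
    if v lies on the path — the path's endpoint counts, the root does not.
    p_s(v) = 1 when the number of such paths strictly exceeds |V(T_s)|/4
    (|V(T_s)| counts the root).  Roots whose tree reaches fewer than two
    other nodes contribute nothing.  On directed networks the trees follow
    edge direction.

    The number of paths meeting v equals the size of v's subtree in T_s
    (every node in the subtree, v included, has its root-path pass through
    v), which is how the counts are accumulated here.
    """
    graph = as_digraph(network)
    bn = {v: 0 for v in graph.nodes}
    for root in sorted(graph.nodes, key=str):
        parent = shortest_path_tree(graph, root)
        tree_size = len(parent)  # includes the root
        if tree_size - 1 < 2:
            continue
        subtree = {v: 1 for v in parent}  # each node's own root-path endpoint
        # Accumulate leaf-to-root: children before parents, i.e. by
        # decreasing depth.  Recompute depths from the parent map.
        depth = {}
        for v in parent:
            d, u = 0, v
            while parent[u] is not None:
                u = parent[u]
                d += 1
            depth[v] = d
        for v in sorted(parent, key=lambda x: -depth[x]):
            if parent[v] is not None:
                subtree[parent[v]] += subtree[v]
        quota = tree_size / 4
        for v in parent:
            if v != root and subtree[v] > quota:
                bn[v] += 1
    return BottleneckTable(scores=bn)


def hierarchical_layers(network) -> LayerAssignment:
    """Assign each node its signal-flow layer.

    Strongly connected components are condensed to super-nodes; a
    super-node's layer is its longest-path depth from the set of
    in-degree-0 super-nodes, and member nodes inherit their component's
    layer.  On an acyclic network every edge therefore goes from a strictly
    lower to a strictly higher layer.
    """
    graph = as_digraph(network)
    if graph.number_of_nodes() == 0:
        raise ValueError("network is empty")
    if not graph.is_directed():
        raise ValueError("hierarchical layering requires a directed network")
    condensation = nx.condensation(graph)
    layer: dict[int, int] = {}
    for comp in nx.topological_sort(condensation):
        preds = list(condensation.predecessors(comp))
        layer[comp] = 0 if not preds else 1 + max(layer[p] for p in preds)
    member_layer = {
        node: layer[comp]
        for comp, data in condensation.nodes(data=True)
        for node in data["members"]
    }
    return LayerAssignment(layers=member_layer)
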
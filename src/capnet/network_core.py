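"""Directed signaling network construction and basic accounting.

A :class:`SignalingNetwork` is a simple directed graph of molecule/event
labels with one typed edge per ordered (source, target) pair.  The build
step applies an explicit :class:`BuildPolicy`: duplicate pairs collapse to a
single edge, self-loops are dropped, and the counts of both are recorded in
the network's provenance so that curation artifacts stay auditable.
Path-based centralities are only well defined on simple graphs, which is why
deduplication is the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import networkx as nx

from .interaction_io import DEFAULT_INTERACTION, InteractionRecord

__all__ = [
    "BuildPolicy",
    "SignalingNetwork",
    "build_network",
    "degree",
    "weakly_connected_components",
    "as_digraph",
    "undirected_projection",
]


@dataclass(frozen=True)
class BuildPolicy:
    """How raw interaction records become graph edges.

    collapse_duplicates:
        Collapse repeated (source, target) pairs to one edge (default on).
    drop_self_loops:
        Drop edges with source == target (default on); every path metric in
        the topology panel is degenerate on self-loops.
    merge_rule_for_labels:
        When duplicates collapse, keep the ``first`` interaction label or
        ``concatenate`` the distinct labels with ``"|"``.
    """

    collapse_duplicates: bool = True
    drop_self_loops: bool = True
    merge_rule_for_labels: Literal["first", "concatenate"] = "first"

    def as_dict(self) -> dict:
        return {
            "collapse_duplicates": self.collapse_duplicates,
            "drop_self_loops": self.drop_self_loops,
            "merge_rule_for_labels": self.merge_rule_for_labels,
        }


@dataclass
class SignalingNetwork:
    """A directed molecular network with typed edges and build provenance."""

    graph: nx.DiGraph
    provenance: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def to_records(self) -> list[InteractionRecord]:
        """Re-express the network's edges as interaction records (sorted)."""
        return [
            InteractionRecord(u, data.get("interaction", DEFAULT_INTERACTION), v)
            for u, v, data in sorted(self.graph.edges(data=True))
        ]

    def __contains__(self, node) -> bool:
        return node in self.graph


def as_digraph(network) -> nx.DiGraph | nx.Graph:
    """Accept a SignalingNetwork or a bare networkx graph; return the graph."""
    return network.graph if isinstance(network, SignalingNetwork) else network


def undirected_projection(network) -> nx.Graph:
    """Simple undirected view: reciprocal directed edges collapse to one."""
    graph = as_digraph(network)
    return graph.to_undirected(as_view=False) if graph.is_directed() else graph


def build_network(
    records: Iterable[InteractionRecord],
    policy: BuildPolicy | None = None,
) -> SignalingNetwork:
    """Assemble a simple directed network from interaction records.

    Nodes are the union of all sources and targets.  The build log in the
    returned network's provenance reports how many duplicate pairs and
    self-loops the policy removed.  Raises ``ValueError`` on an empty record
    collection.
    """
    records = list(records)
    if not records:
        raise ValueError("cannot build a network from an empty record collection")
    policy = policy or BuildPolicy()

    graph = nx.DiGraph()
    n_self_loops_dropped = 0
    n_duplicates_collapsed = 0
    for rec in records:
        u, kind, v = rec.triple
        graph.add_node(u)
        graph.add_node(v)
        if u == v and policy.drop_self_loops:
            n_self_loops_dropped += 1
            continue
        if graph.has_edge(u, v):
            if policy.collapse_duplicates:
                n_duplicates_collapsed += 1
                if policy.merge_rule_for_labels == "concatenate":
                    existing = graph[u][v]["interaction"]
                    if kind not in existing.split("|"):
                        graph[u][v]["interaction"] = f"{existing}|{kind}"
                continue
        graph.add_edge(u, v, interaction=kind)

    provenance = {
        "policy": policy.as_dict(),
        "n_input_records": len(records),
        "n_self_loops_dropped": n_self_loops_dropped,
        "n_duplicates_collapsed": n_duplicates_collapsed,
    }
    return SignalingNetwork(graph=graph, provenance=provenance)


def degree(network, node, mode: Literal["in", "out", "total"] = "total") -> int:
    """Degree of ``node``: incoming, outgoing, or total interaction count."""
    graph = as_digraph(network)
    if node not in graph:
        raise KeyError(f"unknown node: {node!r}")
    if not graph.is_directed():
        return graph.degree(node)
    if mode == "in":
        return graph.in_degree(node)
    if mode == "out":
        return graph.out_degree(node)
    if mode == "total":
        return graph.degree(node)
    raise ValueError(f"mode must be 'in', 'out' or 'total', got {mode!r}")


def weakly_connected_components(network) -> list[set]:
    """Connected components of the undirected projection (largest first).

    A directed pathway with pure input nodes is never strongly connected, so
    "connected components" here means weak components, matching how a single
    connected signaling cascade is counted as one network.
    """
    graph = as_digraph(network)
    if graph.is_directed():
        comps = nx.weakly_connected_components(graph)
    else:
        comps = nx.connected_components(graph)
    return sorted((set(c) for c in comps), key=lambda c: (-len(c), sorted(map(str, c))))
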
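"""Seeded generators for synthetic signaling-like networks.

These generators supply every class of test input the analysis needs:

* ``ba`` — Barabási–Albert preferential-attachment graphs, edges oriented
  from each new node to the existing node it attaches to, so that early
  nodes become in-degree hubs (mirroring signaling convergence onto a few
  controllers).
* ``planted_clusters`` — k dense blocks with sparse between-block edges,
  for cluster-recovery benchmarks.
* ``bridge`` — two cliques sharing a single articulation node, the textbook
  bottleneck topology.
* ``exact_powerlaw`` — a degree histogram following N(k) = round(C·k^γ0)
  exactly, for power-law fit recovery.
* ``fixture_26sn`` — a deterministic stand-in for a small curated
  capacitation-signaling network.  It is synthetic: it reproduces only
  published summary constraints (39 nodes, 47 links, one weak component, a
  single bicarbonate-like input source, three designated controller nodes
  of total degree 13, 9, and 7 that are the network's only hubs) and
  invents no biology beyond those constraints.

All generators are deterministic given their spec (kind, parameters, seed);
the fixture ignores the seed entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np

from .interaction_io import InteractionRecord
from .network_core import BuildPolicy, SignalingNetwork, build_network
from .scale_free_fit import DegreeDistribution

__all__ = ["GeneratorSpec", "generate", "fixture_26sn"]

KINDS = ("ba", "planted_clusters", "bridge", "fixture_26sn", "exact_powerlaw")


@dataclass(frozen=True)
class GeneratorSpec:
    """What to generate: a kind, kind-specific parameters, and a seed."""

    kind: str
    parameters: Mapping = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown generator kind {self.kind!r}; choose from {KINDS}")


def _network_from_edges(edges, kind: str, spec: GeneratorSpec) -> SignalingNetwork:
    records = [InteractionRecord(u, label, v) for u, label, v in edges]
    net = build_network(records, BuildPolicy())
    net.provenance["generator"] = {
        "kind": kind,
        "parameters": dict(spec.parameters),
        "seed": spec.seed,
        "rng": "numpy.random.default_rng (PCG64)",
    }
    return net


def _ba(spec: GeneratorSpec) -> SignalingNetwork:
    n = int(spec.parameters.get("n", 100))
    m = int(spec.parameters.get("m", 1))
    if not 1 <= m < n:
        raise ValueError(f"ba requires 1 <= m < n, got m={m}, n={n}")
    graph = nx.barabasi_albert_graph(n, m, seed=spec.seed)
    width = len(str(n - 1))
    label = lambda i: f"N{i:0{width}d}"
    # Orient new -> existing: the larger index joined later.
    edges = [(label(max(u, v)), "interacts", label(min(u, v))) for u, v in graph.edges]
    return _network_from_edges(sorted(edges), "ba", spec)


def _planted_clusters(spec: GeneratorSpec) -> SignalingNetwork:
    k = int(spec.parameters.get("k_blocks", 3))
    size = int(spec.parameters.get("block_size", 8))
    p_in = float(spec.parameters.get("p_in", 0.9))
    p_out = float(spec.parameters.get("p_out", 0.05))
    if k < 1 or size < 2:
        raise ValueError("planted_clusters requires k_blocks >= 1 and block_size >= 2")
    if not (0 <= p_out <= p_in <= 1):
        raise ValueError("probabilities must satisfy 0 <= p_out <= p_in <= 1")
    rng = np.random.default_rng(spec.seed)
    nodes = [f"B{b}_{i:02d}" for b in range(k) for i in range(size)]
    block = {v: int(v[1 : v.index("_")]) for v in nodes}
    edges = []
    for a in range(len(nodes)):
        for b in range(a + 1, len(nodes)):
            u, v = nodes[a], nodes[b]
            p = p_in if block[u] == block[v] else p_out
            if rng.random() < p:
                edges.append((u, "interacts", v))
    return _network_from_edges(edges, "planted_clusters", spec)


def _bridge(spec: GeneratorSpec) -> SignalingNetwork:
    size = int(spec.parameters.get("clique_size", 5))
    if size < 3:
        raise ValueError("bridge requires clique_size >= 3")
    left = [f"A{i:02d}" for i in range(1, size)]
    right = [f"B{i:02d}" for i in range(1, size)]
    art = "X_bridge"
    edges = []
    for clique in (left + [art], right + [art]):
        ordered = sorted(clique)
        for a in range(len(ordered)):
            for b in range(a + 1, len(ordered)):
                edges.append((ordered[a], "interacts", ordered[b]))
    return _network_from_edges(edges, "bridge", spec)


def _exact_powerlaw(spec: GeneratorSpec) -> DegreeDistribution:
    gamma0 = float(spec.parameters.get("gamma0", -2.0))
    c = float(spec.parameters.get("C", 64.0))
    ks = spec.parameters.get("k", (1, 2, 4, 8))
    bins = {}
    for k in sorted(int(k) for k in ks):
        if k < 1:
            raise ValueError("degrees in an exact power-law histogram must be >= 1")
        count = round(c * k**gamma0)
        if count > 0:
            bins[k] = int(count)
    if len(bins) < 2:
        raise ValueError("exact_powerlaw produced fewer than 2 non-empty bins")
    return DegreeDistribution(mode="total", bins=bins, n_zero_degree=0)


# Designated labels of the deterministic fixture.
FIXTURE_SOURCE = "HCO3-"
FIXTURE_HUBS = ("26S proteasome", "PKA", "Ca2+")


def fixture_26sn() -> SignalingNetwork:
    """Deterministic 39-node / 47-edge capacitation-signaling stand-in.

    An acyclic directed network with a unique in-degree-0 source ("HCO3-"),
    three designated controller nodes with total degrees 13, 9 and 7 (the
    only nodes above the μ + σ hub threshold), one weak component, and no
    reciprocal edge pairs — so the average neighbor count is exactly
    2·47/39 ≈ 2.410.  Everything else about the real curated network is
    deliberately not emulated.
    """
    prot, pka, ca = FIXTURE_HUBS
    m = lambda i: f"M{i:02d}"
    edges: list[tuple[str, str, str]] = [
        (FIXTURE_SOURCE, "activates", m(1)),
        (m(1), "activates", pka),
        (pka, "activates", prot),
        (prot, "activates", m(2)),
        (m(2), "activates", ca),
    ]
    edges += [(prot, "interacts", m(i)) for i in range(3, 14)]   # degree 13
    edges += [(pka, "interacts", m(i)) for i in range(14, 21)]   # degree 9
    edges += [(ca, "interacts", m(i)) for i in range(21, 27)]    # degree 7
    edges += [(m(i), "interacts", m(i + 24)) for i in range(3, 12)]
    downstream = [(20, 27), (21, 28), (22, 29), (14, 30), (15, 31),
                  (16, 32), (17, 33), (18, 34), (19, 35)]
    edges += [(m(a), "interacts", m(b)) for a, b in downstream]
    spec = GeneratorSpec(kind="fixture_26sn", parameters={}, seed=0)
    return _network_from_edges(edges, "fixture_26sn", spec)


def generate(spec: GeneratorSpec):
    """Generate the network (or degree histogram) a spec describes.

    Identical specs — including the seed — produce identical outputs;
    ``fixture_26sn`` ignores the seed and is always the same network.
    """
    if spec.kind == "ba":
        return _ba(spec)
    if spec.kind == "planted_clusters":
        return _planted_clusters(spec)
    if spec.kind == "bridge":
        return _bridge(spec)
    if spec.kind == "fixture_26sn":
        return fixture_26sn()
    if spec.kind == "exact_powerlaw":
        return _exact_powerlaw(spec)
    raise ValueError(f"unknown generator kind: {spec.kind!r}")
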
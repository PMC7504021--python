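"""End-to-end analysis pipeline: read → build → topology → fits → controllers → MCL.

One :class:`AnalysisConfig` drives the whole run, and the effective
configuration is embedded verbatim in the JSON report so every number in it
can be recomputed by calling the underlying operation directly.  Reports
contain no timestamps, so identical runs produce byte-identical output.
"""

from __future__ import annotations

import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

from . import interaction_io
from .controllers import bottleneck_scores, hierarchical_layers, identify_hubs
from .mcl_clustering import MCLParams, mcl_cluster
from .network_core import BuildPolicy, SignalingNetwork, build_network
from .scale_free_fit import degree_distribution, fit_power_law
from .topology_metrics import centrality_table, compute_topology_report

__all__ = ["AnalysisConfig", "PipelineError", "run_analysis", "load_network"]

SCHEMA_VERSION = "1.0"

logger = logging.getLogger("capnet")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class AnalysisConfig:
    """Everything one analysis run depends on."""

    input: str | Path
    format: Literal["sif", "edgelist", "table-csv", "table-tsv"] = "sif"
    policy: BuildPolicy = field(default_factory=BuildPolicy)
    direction: Literal["directed", "undirected"] = "directed"
    degree_mode: Literal["total", "in", "out"] = "total"
    sigma_kind: Literal["population", "sample"] = "population"
    mcl: MCLParams = field(default_factory=MCLParams)
    out_dir: str | Path | None = None
    seed: int = 0
    log_level: str = "INFO"

    def as_dict(self) -> dict:
        return {
            "input": str(self.input),
            "format": self.format,
            "policy": self.policy.as_dict(),
            "direction": self.direction,
            "degree_mode": self.degree_mode,
            "sigma_kind": self.sigma_kind,
            "mcl": {
                "inflation": self.mcl.inflation,
                "expansion": self.mcl.expansion,
                "self_loop_weight": self.mcl.self_loop_weight,
                "prune_threshold": self.mcl.prune_threshold,
                "convergence_tol": self.mcl.convergence_tol,
                "max_iterations": self.mcl.max_iterations,
            },
            "out_dir": str(self.out_dir) if self.out_dir else None,
            "seed": self.seed,
            "log_level": self.log_level,
        }


def load_network(path: str | Path, format: str, policy: BuildPolicy) -> SignalingNetwork:
    """Read a network file in any supported format and build the graph."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as stream:
        if format == "sif":
            records, isolated = interaction_io.read_sif(stream)
            net = build_network(records, policy)
            net.graph.add_nodes_from(isolated)
            return net
        if format == "edgelist":
            records = interaction_io.read_edge_list(stream)
        elif format == "table-csv":
            records = interaction_io.parse_interaction_table(stream, dialect="comma")
        elif format == "table-tsv":
            records = interaction_io.parse_interaction_table(stream, dialect="tab")
        else:
            raise ValueError(f"unknown input format: {format!r}")
    return build_network(records, policy)


def _degree_fit(network, mode: str) -> dict:
    dist = degree_distribution(network, mode=mode)
    try:
        fit = fit_power_law(dist)
    except ValueError:
        return {"gamma": None, "r": None, "r2": None, "n_points": len(dist.bins)}
    return {"gamma": fit.gamma, "r": fit.r, "r2": fit.r2, "n_points": fit.n_points}


def analyze_network(network: SignalingNetwork, config: AnalysisConfig) -> dict:
    """Run every analysis stage on an in-memory network; return the report."""
    report: dict = {"schema_version": SCHEMA_VERSION, "config": config.as_dict()}
    report["provenance"] = network.provenance

    logger.info("topology panel (%s mode)", config.direction)
    topo = compute_topology_report(network, direction=config.direction)
    graph = network.graph
    degrees = sorted(
        ((v, graph.degree(v)) for v in graph.nodes), key=lambda kv: (-kv[1], str(kv[0]))
    )
    report["topology"] = {
        **topo.as_dict(),
        "in_degree_fit": _degree_fit(network, "in"),
        "out_degree_fit": _degree_fit(network, "out"),
        "most_connected_nodes": [
            {"node": str(v), "degree": int(d)} for v, d in degrees[:3]
        ],
    }

    logger.info("centralities")
    cent = centrality_table(network)
    report["centrality"] = {
        str(v): {k: (float(x) if k in ("betweenness", "closeness") else int(x))
                 for k, x in row.items()}
        for v, row in cent.frame.iterrows()
    }

    logger.info("hubs / bottlenecks / layers")
    hubs = identify_hubs(network, degree_mode=config.degree_mode, sigma_kind=config.sigma_kind)
    report["hubs"] = {
        "mu": hubs.mu,
        "sigma": hubs.sigma,
        "threshold": hubs.threshold,
        "hubs": {str(v): int(d) for v, d in sorted(hubs.hubs.items(), key=lambda kv: str(kv[0]))},
    }
    bn = bottleneck_scores(network)
    report["bottlenecks"] = {str(v): int(s) for v, s in sorted(bn.scores.items(), key=lambda kv: str(kv[0]))}
    layers = hierarchical_layers(network)
    report["layers"] = {str(v): int(l) for v, l in sorted(layers.layers.items(), key=lambda kv: str(kv[0]))}

    logger.info("MCL clustering (inflation %.3g)", config.mcl.inflation)
    clusters = mcl_cluster(network, config.mcl)
    report["clusters"] = {
        "n_clusters": len(clusters.clusters),
        "converged": clusters.converged,
        "n_iterations": clusters.n_iterations,
        "assignment": {str(v): int(i) for v, i in sorted(clusters.labels().items(), key=lambda kv: str(kv[0]))},
    }
    return report


def _write_outputs(report: dict, network: SignalingNetwork, config: AnalysisConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with (out / "report.json").open("w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    cent = centrality_table(network)
    with (out / "centrality.tsv").open("w", encoding="utf-8") as fh:
        cent.to_tsv(fh)
    with (out / "nodes.tsv").open("w", encoding="utf-8") as fh:
        fh.write("node\tdegree\tbn\tis_hub\tlayer\n")
        hubs = set(report["hubs"]["hubs"])
        for v in sorted(network.graph.nodes, key=str):
            fh.write(
                f"{v}\t{network.graph.degree(v)}\t{report['bottlenecks'][str(v)]}\t"
                f"{str(v) in hubs}\t{report['layers'][str(v)]}\n"
            )
    with (out / "clusters.tsv").open("w", encoding="utf-8") as fh:
        fh.write("node\tcluster_id\n")
        for v, i in sorted(report["clusters"]["assignment"].items()):
            fh.write(f"{v}\t{i}\n")


def run_analysis(config: AnalysisConfig) -> dict:
    """Run the full pipeline per ``config``; return (and optionally write) the report.

    On any stage failure a :class:`PipelineError` naming the stage is raised
    and partially written outputs are removed.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    stage = "read"
    try:
        network = load_network(config.input, config.format, config.policy)
        stage = "analyze"
        report = analyze_network(network, config)
        if config.out_dir is not None:
            stage = "write"
            _write_outputs(report, network, config)
        return report
    except Exception as exc:
        if config.out_dir is not None and Path(config.out_dir).exists() and stage == "write":
            shutil.rmtree(config.out_dir, ignore_errors=True)
        raise PipelineError(stage, exc) from exc
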
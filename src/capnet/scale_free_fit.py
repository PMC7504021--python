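"""Degree distributions and power-law exponent fitting.

A scale-free network has a degree distribution N(k) ∝ k^γ with γ < 0.  The
fit here is the classical network-analyzer procedure: take the raw histogram
of node counts N(k) over positive degrees k, drop empty bins, and fit a
least-squares line to log N(k) against log k.  The slope is the exponent γ,
and the Pearson correlation r (with R² = r²) of the logged points measures
adherence to the power law.  The exponent is invariant to the logarithm base
and to rescaling the counts, both of which only move the intercept.

This is deliberately the regression procedure, not maximum-likelihood
(Clauset-style) estimation: it is the convention used when reporting γ, r
and R² side by side for small curated networks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
from scipy import stats

from .network_core import as_digraph

__all__ = [
    "DegreeDistribution",
    "PowerLawFit",
    "degree_distribution",
    "fit_power_law",
]


@dataclass(frozen=True)
class DegreeDistribution:
    """Histogram of node counts by degree, for one degree mode.

    ``bins`` maps degree k (positive integer) to the number of nodes N(k)
    with that degree; zero-count bins are absent.  ``n_zero_degree`` records
    how many nodes had degree 0 in this mode (excluded from the bins, since
    log 0 is undefined, but kept for accounting).
    """

    mode: Literal["in", "out", "total"]
    bins: Mapping[int, int]
    n_zero_degree: int = 0

    def __post_init__(self) -> None:
        for k, count in self.bins.items():
            if k <= 0 or count <= 0:
                raise ValueError(f"bins must map positive degrees to positive counts, got {k}: {count}")


@dataclass(frozen=True)
class PowerLawFit:
    """Least-squares power-law fit on logarithmized degree histogram points."""

    gamma: float
    r: float
    r2: float
    n_points: int


def degree_distribution(
    network, mode: Literal["in", "out", "total"] = "total"
) -> DegreeDistribution:
    """Exact histogram of the selected degree mode.

    Zero-degree nodes are excluded from the bins and counted in
    ``n_zero_degree``.
    """
    graph = as_digraph(network)
    if graph.number_of_nodes() == 0:
        raise ValueError("network is empty")
    if not graph.is_directed():
        degrees = dict(graph.degree())
    elif mode == "in":
        degrees = dict(graph.in_degree())
    elif mode == "out":
        degrees = dict(graph.out_degree())
    elif mode == "total":
        degrees = dict(graph.degree())
    else:
        raise ValueError(f"mode must be 'in', 'out' or 'total', got {mode!r}")
    bins: dict[int, int] = {}
    n_zero = 0
    for d in degrees.values():
        if d == 0:
            n_zero += 1
        else:
            bins[d] = bins.get(d, 0) + 1
    return DegreeDistribution(mode=mode, bins=dict(sorted(bins.items())), n_zero_degree=n_zero)


def fit_power_law(dist: DegreeDistribution) -> PowerLawFit:
    """Fit log10 N(k) against log10 k by least squares.

    gamma is the slope, r the Pearson correlation of the logged points, and
    r2 = r².  Requires at least two distinct positive degrees; raises
    ``ValueError`` otherwise.
    """
    ks = np.array(sorted(dist.bins), dtype=float)
    if ks.size < 2:
        raise ValueError(
            f"power-law fit needs >= 2 distinct positive degrees, got {ks.size}"
        )
    counts = np.array([dist.bins[int(k)] for k in ks], dtype=float)
    log_k = np.log10(ks)
    log_n = np.log10(counts)
    fit = stats.linregress(log_k, log_n)
    # Constant log-counts give a perfectly flat line: slope 0, correlation 0.
    r = 0.0 if np.ptp(log_n) == 0 else float(fit.rvalue)
    return PowerLawFit(gamma=float(fit.slope), r=r, r2=r * r, n_points=int(ks.size))
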
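"""Degree-distribution and clustering diagnostics.

Classifies a network along two standard axes: scale-free (power-law degree
distribution, diagnosed by an ordinary least-squares fit of log10 P(k) on
log10 k) and hierarchical (average clustering coefficient decaying roughly
as C(k) ∝ 1/k; a flat profile means *not* hierarchical).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats


@dataclass(frozen=True)
class DegreeDistribution:
    """Normalised degree histogram: pk[k] = fraction of nodes with degree k."""

    pk: dict[int, float]

    @property
    def support(self) -> list[int]:
        return sorted(self.pk)


@dataclass(frozen=True)
class PowerLawFit:
    exponent: float      # slope of log10 P(k) vs log10 k
    intercept: float
    pearson_r: float
    r_squared: float
    n_points: int


@dataclass(frozen=True)
class ClusteringProfile:
    per_node: dict
    by_degree: dict[int, float]   # mean C over nodes of degree k (k >= 2)
    overall_mean: float
    overall_sd: float


def degree_distribution(graph: nx.Graph) -> DegreeDistribution:
    """Normalised histogram of node degrees (isolates count at k=0)."""
    n = graph.number_of_nodes()
    if n == 0:
        raise ValueError("degree distribution of an empty graph is undefined")
    counts = Counter(d for _, d in graph.degree())
    return DegreeDistribution(pk={k: c / n for k, c in sorted(counts.items())})


def fit_power_law(dist: DegreeDistribution,
                  outlier_sigma: float | None = None) -> PowerLawFit:
    """OLS fit of log10 P(k) on log10 k over the support with k >= 1.

    If ``outlier_sigma`` is given, one round of refitting is performed
    after removing points whose standardised residual exceeds it in
    absolute value.  Reports the slope (the power-law exponent), Pearson r
    of the log-log points, and R² = 1 − SSres/SStot (equal to r² for a
    straight-line fit with intercept).
    """
    ks = [k for k in dist.support if k >= 1]
    if len(ks) < 3:
        raise ValueError("need at least 3 support points with k >= 1 to fit")
    x = np.log10(ks)
    y = np.log10([dist.pk[k] for k in ks])

    res = stats.linregress(x, y)
    if outlier_sigma is not None:
        resid = y - (res.intercept + res.slope * x)
        dof = max(len(x) - 2, 1)
        s = float(np.sqrt(np.sum(resid**2) / dof))
        if s > 0:
            keep = np.abs(resid / s) <= outlier_sigma
            if keep.sum() >= 3 and not keep.all():
                x, y = x[keep], y[keep]
                res = stats.linregress(x, y)

    return PowerLawFit(
        exponent=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        r_squared=float(res.rvalue**2),
        n_points=len(x),
    )


def clustering_profile(graph: nx.Graph) -> ClusteringProfile:
    """Per-node clustering coefficients C_i = 2n/[k_i(k_i−1)] and the
    degree-conditional means.

    Nodes of degree <= 1 get C_i = 0 by convention and are excluded from
    the by-degree means (the coefficient is 0/0 there).  The overall mean
    and population standard deviation run over all nodes.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("clustering profile of an empty graph is undefined")
    per_node = nx.clustering(graph)
    by_deg: dict[int, list[float]] = {}
    for node, c in per_node.items():
        k = graph.degree(node)
        if k >= 2:
            by_deg.setdefault(k, []).append(c)
    values = np.fromiter(per_node.values(), dtype=float)
    return ClusteringProfile(
        per_node=dict(per_node),
        by_degree={k: float(np.mean(v)) for k, v in sorted(by_deg.items())},
        overall_mean=float(values.mean()),
        overall_sd=float(values.std()),
    )


def hierarchy_slope(profile: ClusteringProfile) -> float:
    """Slope of log10 C(k) on log10 k over degrees with mean C > 0.

    ≈ −1 for a hierarchical network (C(k) ∝ 1/k), ≈ 0 when clustering is
    degree-independent.
    """
    pts = [(k, c) for k, c in profile.by_degree.items() if c > 0]
    if len(pts) < 3:
        raise ValueError("need at least 3 positive by-degree points")
    x = np.log10([k for k, _ in pts])
    y = np.log10([c for _, c in pts])
    return float(stats.linregress(x, y).slope)


def diameter(graph: nx.Graph) -> int:
    """Maximum finite shortest-path distance.

    On a disconnected graph the diameter of the largest connected
    component is returned (ties broken arbitrarily by networkx order).
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("diameter of an empty graph is undefined")
    if nx.is_connected(graph):
        return nx.diameter(graph)
    giant = max(nx.connected_components(graph), key=len)
    return nx.diameter(graph.subgraph(giant))
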
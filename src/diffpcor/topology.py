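"""Topological characterization of association and differential networks.

Per-node measures: degree k_i; betweenness centrality b_i (unnormalized
undirected Freeman counts by default — each unordered source-target pair
contributes the fraction of its shortest paths passing through the node);
clustering coefficient c_i = K_i / (k_i (k_i - 1) / 2) with K_i the edges
among the neighbors of i, defined as 0 for k_i < 2.

Network-level measures: connected / isolated node counts, edge count E,
density 2E / (N (N-1)), average degree 2E / N over all N nodes including
isolated ones, the degree distribution P(k) = count(k) / N for observed
k >= 1, and the least-squares slope of P(k) against k on a chosen scale
(log-log by default, the power-law reading).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "TopologySummary",
    "degrees",
    "degree_distribution",
    "degree_slope",
    "betweenness",
    "clustering",
    "global_summary",
    "format_summary",
]


def _as_graph(network) -> nx.Graph:
    if isinstance(network, nx.Graph):
        return network
    if hasattr(network, "to_networkx"):
        return network.to_networkx()
    raise TypeError(f"expected a network, got {type(network).__name__}")


def degrees(network) -> dict[str, int]:
    """Connections per node, zeros included for isolated nodes."""
    g = _as_graph(network)
    return {node: int(k) for node, k in g.degree()}


def degree_distribution(node_degrees) -> dict[int, float]:
    """P(k) = (#nodes with degree k) / N over observed k >= 1.

    Isolated nodes count in the denominator N but receive no P(k) entry.
    """
    if isinstance(node_degrees, dict):
        vals = list(node_degrees.values())
    else:
        vals = list(node_degrees)
    n = len(vals)
    if n == 0:
        return {}
    ks, counts = np.unique([v for v in vals if v >= 1], return_counts=True)
    return {int(k): float(c) / n for k, c in zip(ks, counts)}


def degree_slope(distribution: dict[int, float], scale: str = "log-log") -> float:
    """Least-squares slope of P(k) against k on the chosen scale.

    ``log-log`` regresses log P(k) on log k (power-law exponent);
    ``semilog`` regresses log P(k) on k; ``linear`` regresses P(k) on k.
    Only support points with P(k) > 0 enter the fit.
    """
    pts = [(k, p) for k, p in distribution.items() if p > 0 and k >= 1]
    if len(pts) < 2:
        raise ValueError("need at least 2 degrees with P(k) > 0 to fit a slope")
    k = np.array([p[0] for p in pts], dtype=float)
    p = np.array([p[1] for p in pts], dtype=float)
    if scale == "log-log":
        x, y = np.log(k), np.log(p)
    elif scale == "semilog":
        x, y = k, np.log(p)
    elif scale == "linear":
        x, y = k, p
    else:
        raise ValueError(f"unknown slope scale {scale!r}")
    slope, _ = np.polyfit(x, y, 1)
    return float(slope)


def betweenness(network, normalized: bool = False) -> dict[str, float]:
    """Betweenness centrality b_v per node.

    Unnormalized (default): the sum over unordered source-target pairs
    (s, t), s != v != t, of sigma_st(v) / sigma_st, where sigma_st counts
    shortest s-t paths and sigma_st(v) those through v; pairs in
    different components contribute 0.
    """
    g = _as_graph(network)
    return {
        node: float(b)
        for node, b in nx.betweenness_centrality(g, normalized=normalized).items()
    }


def clustering(network) -> dict[str, float]:
    """Clustering coefficient c_i per node; c_i = 0 whenever k_i < 2."""
    g = _as_graph(network)
    return {node: float(c) for node, c in nx.clustering(g).items()}


@dataclass
class TopologySummary:
    """Per-node and network-level topological properties."""

    per_node: pd.DataFrame  # node, degree, betweenness, clustering
    n_nodes: int
    n_connected: int
    n_isolated: int
    n_edges: int
    density: float
    average_degree: float
    degree_dist: dict[int, float]
    slope: float | None
    slope_scale: str
    mean_clustering: float
    hubs: list[str] = field(default_factory=list)


def global_summary(
    network,
    slope_scale: str = "log-log",
    normalized_betweenness: bool = False,
    n_hubs: int = 5,
) -> TopologySummary:
    """All per-node and global topology measures of one network.

    The degree-distribution slope is ``None`` when fewer than two degrees
    have positive probability.  Hubs are nodes ranked by degree, ties
    broken by betweenness.
    """
    g = _as_graph(network)
    degs = degrees(g)
    btw = betweenness(g, normalized=normalized_betweenness)
    clust = clustering(g)
    nodes = list(g.nodes)
    n = len(nodes)
    e = g.number_of_edges()
    per_node = pd.DataFrame(
        {
            "node": nodes,
            "degree": [degs[v] for v in nodes],
            "betweenness": [btw[v] for v in nodes],
            "clustering": [clust[v] for v in nodes],
        }
    )
    dist = degree_distribution(degs)
    try:
        slope = degree_slope(dist, slope_scale)
    except ValueError:
        slope = None
    ranked = sorted(nodes, key=lambda v: (-degs[v], -btw[v], nodes.index(v)))
    return TopologySummary(
        per_node=per_node,
        n_nodes=n,
        n_connected=sum(1 for v in nodes if degs[v] > 0),
        n_isolated=sum(1 for v in nodes if degs[v] == 0),
        n_edges=e,
        density=2.0 * e / (n * (n - 1)) if n > 1 else 0.0,
        average_degree=2.0 * e / n if n else 0.0,
        degree_dist=dist,
        slope=slope,
        slope_scale=slope_scale,
        mean_clustering=float(np.mean([clust[v] for v in nodes])) if nodes else 0.0,
        hubs=ranked[:n_hubs],
    )


def format_summary(ts: TopologySummary) -> str:
    """Labeled text block of the global network properties."""
    slope = "n/a" if ts.slope is None else f"{ts.slope:.3f} ({ts.slope_scale})"
    lines = [
        f"Connected nodes              {ts.n_connected}",
        f"Isolated nodes               {ts.n_isolated}",
        f"Total number of edges        {ts.n_edges}",
        f"Network density              {ts.density:.3f}",
        f"Average degree               {ts.average_degree:.2f}",
        f"Slope of degree distribution {slope}",
        f"Clustering coefficient       {ts.mean_clustering:.2f}",
        f"Top hubs                     {', '.join(str(h) for h in ts.hubs)}",
    ]
    return "\n".join(lines)
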
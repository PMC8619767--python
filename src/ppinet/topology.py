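"""Network topography statistics, hub/bottleneck backbone, edge enrichment.

The statistics follow the Cytoscape Network Analyzer conventions: average
local clustering over all nodes (degree < 2 contributes 0), diameter /
radius / characteristic path length on the largest connected component,
heterogeneity as the coefficient of variation of the degree distribution
(population variance), and shortest-path betweenness normalized by
(n-1)(n-2)/2 so the center of a star scores 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

__all__ = [
    "TopologyReport",
    "Backbone",
    "EdgeEnrichment",
    "topology_report",
    "betweenness",
    "extract_backbone",
    "edge_enrichment",
]

#: Reporting floor for the edge-enrichment p-value.
P_FLOOR = 1.0e-16


@dataclass(frozen=True)
class TopologyReport:
    n_nodes: int
    n_edges: int
    avg_degree: float
    density: float
    avg_local_clustering: float
    diameter: int
    radius: int
    char_path_length: float
    heterogeneity: float
    n_components: int
    degree: dict[str, int] = field(repr=False)
    betweenness: dict[str, float] = field(repr=False)


@dataclass(frozen=True)
class Backbone:
    """Top hubs (highest degree) and top non-hub bottlenecks (highest betweenness)."""

    hubs: tuple[tuple[str, int], ...]
    non_hub_bottlenecks: tuple[tuple[str, float], ...]


@dataclass(frozen=True)
class EdgeEnrichment:
    observed: int
    expected: float
    p_value: float


def betweenness(net: nx.Graph) -> dict[str, float]:
    """Normalized shortest-path betweenness centrality for every node.

    Shortest paths of equal length split their contribution evenly; the
    divisor (n-1)(n-2)/2 anchors the center of a star at 1.
    """
    if net.number_of_nodes() < 3:
        raise ValueError("betweenness requires at least 3 nodes")
    return {n: float(b) for n, b in nx.betweenness_centrality(net, normalized=True).items()}


def topology_report(net: nx.Graph) -> TopologyReport:
    """Compute the full set of topography statistics for a network."""
    n = net.number_of_nodes()
    if n < 2:
        raise ValueError("topology_report requires at least 2 nodes")
    m = net.number_of_edges()
    degrees = dict(net.degree())
    deg = np.array([degrees[v] for v in net.nodes()], dtype=float)
    mean_deg = deg.mean()
    heterogeneity = 0.0 if mean_deg == 0 else float(np.sqrt(deg.var()) / mean_deg)

    components = list(nx.connected_components(net))
    giant = net.subgraph(max(components, key=len))
    if giant.number_of_nodes() >= 2:
        diameter = nx.diameter(giant)
        radius = nx.radius(giant)
        cpl = nx.average_shortest_path_length(giant)
    else:
        diameter = radius = 0
        cpl = 0.0

    btw = (
        {v: 0.0 for v in net.nodes()}
        if n < 3
        else betweenness(net)
    )
    return TopologyReport(
        n_nodes=n,
        n_edges=m,
        avg_degree=2.0 * m / n,
        density=2.0 * m / (n * (n - 1)),
        avg_local_clustering=nx.average_clustering(net),
        diameter=int(diameter),
        radius=int(radius),
        char_path_length=float(cpl),
        heterogeneity=heterogeneity,
        n_components=len(components),
        degree=degrees,
        betweenness=btw,
    )


def extract_backbone(net: nx.Graph, n_hubs: int = 6, n_bottlenecks: int = 2) -> Backbone:
    """Extract the network backbone: top hubs plus top non-hub bottlenecks.

    Hubs are the ``n_hubs`` highest-degree nodes (ties broken by betweenness
    descending, then identifier ascending); bottlenecks are the
    ``n_bottlenecks`` highest-betweenness nodes among the remainder.
    """
    if n_hubs + n_bottlenecks > net.number_of_nodes():
        raise ValueError("n_hubs + n_bottlenecks exceeds the node count")
    degrees = dict(net.degree())
    btw = (
        {v: 0.0 for v in net.nodes()}
        if net.number_of_nodes() < 3
        else betweenness(net)
    )
    by_degree = sorted(net.nodes(), key=lambda v: (-degrees[v], -btw[v], v))
    hubs = by_degree[:n_hubs]
    rest = [v for v in net.nodes() if v not in set(hubs)]
    by_btw = sorted(rest, key=lambda v: (-btw[v], v))
    bottlenecks = by_btw[:n_bottlenecks]
    return Backbone(
        hubs=tuple((v, degrees[v]) for v in hubs),
        non_hub_bottlenecks=tuple((v, btw[v]) for v in bottlenecks),
    )


def edge_enrichment(net: nx.Graph, background_density: float) -> EdgeEnrichment:
    """Upper-tail binomial test of the observed edge count against a background.

    Under the null every one of the C(n, 2) node pairs is an edge
    independently with probability ``background_density``; the p-value is
    P(X >= observed), floored at 1e-16 to mirror the usual reporting
    convention.  This density null is an approximation of database nulls
    that condition on node degrees.
    """
    if not 0.0 < background_density < 1.0:
        raise ValueError("background_density must be in (0, 1)")
    n = net.number_of_nodes()
    pairs = n * (n - 1) // 2
    observed = net.number_of_edges()
    expected = pairs * background_density
    p = float(stats.binom.sf(observed - 1, pairs, background_density))
    return EdgeEnrichment(observed=observed, expected=expected, p_value=max(p, P_FLOOR))
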
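"""Molecular Complex Detection (MCODE).

Three stages, operating on topology only (edge confidences are ignored):

1. Vertex weighting — each node's weight is the core-clustering
   coefficient of its closed neighborhood: k x density of the highest
   k-core of the subgraph induced on the node and its neighbors.
2. Complex prediction — greedy seeded expansion from the highest-weight
   unvisited node, including neighbors whose weight is within a vertex
   weight percentage (vwp) of the seed's.
3. Post-processing — haircut (iteratively strip members with fewer than
   two intra-complex connections) and optional fluff; complexes below the
   minimum size are dropped.

Complexes are node-disjoint, scored by density x size, and returned in
descending score order.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

__all__ = ["MCODEParams", "Complex", "mcode_weights", "mcode_complexes"]


@dataclass(frozen=True)
class MCODEParams:
    vwp: float = 0.2
    haircut: bool = True
    fluff: bool = False
    fluff_density: float = 0.1
    min_complex_size: int = 3

    def __post_init__(self) -> None:
        if not 0.0 <= self.vwp < 1.0:
            raise ValueError("vwp must be in [0, 1)")
        if self.min_complex_size < 1:
            raise ValueError("min_complex_size must be >= 1")


@dataclass(frozen=True)
class Complex:
    members: frozenset[str]
    score: float
    seed_node: str


def _density(graph: nx.Graph) -> float:
    n = graph.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * graph.number_of_edges() / (n * (n - 1))


def mcode_weights(net: nx.Graph) -> dict[str, float]:
    """Core-clustering vertex weights: k x density of the highest k-core
    of each node's closed neighborhood.  Isolated nodes weigh 0."""
    weights: dict[str, float] = {}
    for v in net.nodes():
        nbhd = set(net.adj[v]) | {v}
        if len(nbhd) < 2:
            weights[v] = 0.0
            continue
        sub = net.subgraph(nbhd)
        core = nx.core_number(sub)
        k = max(core.values())
        kcore = sub.subgraph([u for u, c in core.items() if c >= k])
        weights[v] = k * _density(kcore)
    return weights


def mcode_complexes(
    net: nx.Graph, params: MCODEParams = MCODEParams()
) -> list[Complex]:
    """Predict dense complexes by greedy seeded expansion.

    Seeds are taken at the highest-weight unvisited node (ties broken by
    smaller identifier); breadth-first expansion includes unvisited
    neighbors with weight >= (1 - vwp) x seed weight, marking every
    included node visited so complexes never share nodes.  Haircut and
    fluff post-processing follow, then complexes smaller than
    ``min_complex_size`` are dropped and the rest ranked by score
    (density x size) descending.
    """
    weights = mcode_weights(net)
    order = sorted(net.nodes(), key=lambda v: (-weights[v], v))
    visited: set[str] = set()
    complexes: list[Complex] = []
    for seed in order:
        if seed in visited or weights[seed] <= 0.0:
            continue
        threshold = (1.0 - params.vwp) * weights[seed]
        members = {seed}
        frontier = [seed]
        visited.add(seed)
        while frontier:
            nxt: list[str] = []
            for v in frontier:
                for u in sorted(net.adj[v]):
                    if u in visited or weights[u] < threshold:
                        continue
                    visited.add(u)
                    members.add(u)
                    nxt.append(u)
            frontier = nxt
        if params.haircut:
            members = _haircut(net, members)
        if params.fluff:
            members = _fluff(net, members, params.fluff_density, visited)
            visited |= members
        if len(members) < params.min_complex_size:
            continue
        sub = net.subgraph(members)
        complexes.append(
            Complex(
                members=frozenset(members),
                score=_density(sub) * len(members),
                seed_node=seed,
            )
        )
    complexes.sort(key=lambda c: (-c.score, c.seed_node))
    return complexes


def _haircut(net: nx.Graph, members: set[str]) -> set[str]:
    """Iteratively remove members with fewer than 2 intra-complex links."""
    members = set(members)
    while members:
        sub = net.subgraph(members)
        trim = {v for v in members if sub.degree(v) < 2}
        if not trim:
            break
        members -= trim
    return members


def _fluff(
    net: nx.Graph, members: set[str], fluff_density: float, visited: set[str]
) -> set[str]:
    """Add unvisited boundary neighbors whose closed-neighborhood density
    exceeds ``fluff_density``."""
    added = set()
    for v in sorted(members):
        for u in net.adj[v]:
            if u in members or u in visited or u in added:
                continue
            nbhd = net.subgraph(set(net.adj[u]) | {u})
            if _density(nbhd) > fluff_density:
                added.add(u)
    return members | added
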
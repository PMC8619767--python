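"""Markov Clustering (MCL) and inter-cluster switch detection.

MCL iterates expansion (matrix power of a column-stochastic transition
matrix, simulating random-walk flow) and inflation (entrywise power plus
renormalization, which sharpens flow towards attractors) until the matrix
stops changing; clusters are read off as connected components of the
nonzero structure of the limit matrix.  The inflation parameter controls
granularity — larger values give more, smaller clusters.

Switches are nodes with many high-confidence connections to the seed
proteins of both of two clusters; they bridge subnetworks and are scored
as min(connections to A-seeds, connections to B-seeds).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse import csgraph

from .io import SeedSet

log = logging.getLogger(__name__)

__all__ = ["MCLParams", "Clustering", "SwitchRow", "SwitchReport", "mcl", "find_switches"]


@dataclass(frozen=True)
class MCLParams:
    """MCL iteration parameters.

    inflation
        Entrywise power (> 1); granularity knob.  3 and 3.4 are the values
        used for the stroke networks this package reproduces.
    expansion
        Matrix-power exponent (integer >= 2).
    prune_threshold
        Entries below this are zeroed after each inflation (the per-column
        maximum is never pruned, keeping columns stochastic).
    tolerance
        Convergence: stop when the largest absolute entry change falls
        below this.
    self_loop
        "max_weight": each node gets a self-loop equal to its maximum
        incident confidence (1.0 for isolated nodes); "unit": all 1.0.
    """

    inflation: float = 3.0
    expansion: int = 2
    prune_threshold: float = 1e-5
    tolerance: float = 1e-8
    max_iterations: int = 200
    self_loop: str = "max_weight"

    def __post_init__(self) -> None:
        if self.inflation <= 1:
            raise ValueError("inflation must be > 1")
        if self.expansion < 2:
            raise ValueError("expansion must be >= 2")
        if self.self_loop not in ("max_weight", "unit"):
            raise ValueError(f"unknown self_loop policy {self.self_loop!r}")


@dataclass(frozen=True)
class Clustering:
    """A hard partition of the network nodes.

    Cluster ids run 1..n_clusters, ordered by descending cluster size and
    then by smallest member identifier.
    """

    assignment: dict[str, int]
    n_clusters: int
    converged: bool
    iterations: int

    def members(self, cluster_id: int) -> set[str]:
        return {v for v, c in self.assignment.items() if c == cluster_id}


def _transition_matrix(net: nx.Graph, nodes: list[str], params: MCLParams) -> np.ndarray:
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    A = np.zeros((n, n))
    for a, b, d in net.edges(data=True):
        A[index[a], index[b]] = A[index[b], index[a]] = d["confidence"]
    if params.self_loop == "unit":
        np.fill_diagonal(A, 1.0)
    else:
        loop = A.max(axis=0)
        loop[loop == 0.0] = 1.0
        np.fill_diagonal(A, loop)
    return A / A.sum(axis=0)


def _normalize_and_prune(M: np.ndarray, threshold: float) -> np.ndarray:
    M = M / M.sum(axis=0)
    keep = M >= threshold
    keep[M.argmax(axis=0), np.arange(M.shape[1])] = True  # never prune the column max
    M = np.where(keep, M, 0.0)
    return M / M.sum(axis=0)


def mcl(net: nx.Graph, params: MCLParams = MCLParams()) -> Clustering:
    """Cluster a confidence-weighted network by Markov Clustering.

    Builds the self-looped weighted adjacency, column-normalizes, then
    alternates expansion and inflation with pruning until convergence.
    Clusters are the connected components of the nonzero structure of the
    limit matrix, numbered by descending size then smallest member.
    """
    nodes = sorted(net.nodes())
    if not nodes:
        raise ValueError("cannot cluster an empty network")
    M = _transition_matrix(net, nodes, params)
    converged = False
    iterations = 0
    for iterations in range(1, params.max_iterations + 1):
        prev = M
        M = np.linalg.matrix_power(M, params.expansion)
        M = _normalize_and_prune(M ** params.inflation, params.prune_threshold)
        if np.abs(M - prev).max() < params.tolerance:
            converged = True
            break
    if not converged:
        log.warning("MCL did not converge in %d iterations", params.max_iterations)

    groups = _read_clusters(M, nodes)
    ordered = sorted(groups, key=lambda g: (-len(g), min(g)))
    assignment = {v: cid for cid, group in enumerate(ordered, start=1) for v in group}
    return Clustering(
        assignment=assignment,
        n_clusters=len(ordered),
        converged=converged,
        iterations=iterations,
    )


def _read_clusters(M: np.ndarray, nodes: list[str]) -> list[list[str]]:
    """Interpret the MCL limit matrix as a hard partition.

    Attractors (nodes with nonzero diagonal mass) form attractor systems —
    connected components of the limit structure restricted to attractors.
    Every other node joins the system receiving most of its column mass;
    a node attracted equally to several systems (an overlapping member in
    classical MCL) goes to the one containing the smallest identifier.
    """
    n = len(nodes)
    attractors = [i for i in range(n) if M[i, i] > 0]
    if not attractors:  # degenerate; treat every node as its own attractor
        attractors = list(range(n))
    sub = M[np.ix_(attractors, attractors)]
    structure = (sub > 0) | (sub > 0).T
    _, labels = csgraph.connected_components(structure, directed=False)
    systems: dict[int, list[int]] = {}
    for pos, lab in zip(attractors, labels):
        systems.setdefault(int(lab), []).append(pos)
    system_list = sorted(systems.values(), key=lambda s: min(nodes[i] for i in s))

    groups: dict[int, list[str]] = {k: [nodes[i] for i in s]
                                    for k, s in enumerate(system_list)}
    attractor_set = set(attractors)
    for j in range(n):
        if j in attractor_set:
            continue
        masses = [sum(M[i, j] for i in s) for s in system_list]
        best = max(masses)
        if best > 0:
            target = masses.index(best)  # first hit = smallest-member system
            groups[target].append(nodes[j])
        else:  # no flow left toward any attractor: keep the node separate
            groups[len(groups)] = [nodes[j]]
    return [sorted(g) for g in groups.values() if g]


@dataclass(frozen=True)
class SwitchRow:
    node: str
    conn_a: int
    conn_b: int
    switch_score: int
    conn_a_07: int
    conn_b_07: int
    conn_a_09: int
    conn_b_09: int


@dataclass(frozen=True)
class SwitchReport:
    rows: tuple[SwitchRow, ...]
    top_switches: tuple[str, ...]
    threshold: float


def _count_links(net: nx.Graph, v: str, targets: set[str], tau: float) -> int:
    if v not in net:
        return 0
    return sum(
        1
        for nbr, d in net.adj[v].items()
        if nbr != v and nbr in targets and d["confidence"] > tau
    )


def find_switches(
    net: nx.Graph,
    clustering: Clustering,
    seeds: SeedSet,
    cluster_a: int,
    cluster_b: int,
    tau: float = 0.4,
    top_k: int = 2,
) -> SwitchReport:
    """Score every node as an inter-cluster switch between two clusters.

    For each node, seed members of ``cluster_a`` and ``cluster_b`` linked
    with confidence strictly above ``tau`` are counted (the node itself is
    excluded); the switch score is the minimum of the two counts, so a
    switch needs connections in both clusters.  Counts at the 0.7 and 0.9
    confidence tiers are emitted as supplementary columns.  The top list is
    ranked by score descending, then total connections descending, then
    identifier.
    """
    if cluster_a == cluster_b:
        raise ValueError("cluster_a and cluster_b must differ")
    present = set(clustering.assignment.values())
    for cid in (cluster_a, cluster_b):
        if cid not in present:
            raise ValueError(f"unknown cluster id {cid}")
    if not 0.0 <= tau <= 1.0:
        raise ValueError(f"tau {tau} outside [0, 1]")
    seed_members = set(seeds.members)
    seeds_a = clustering.members(cluster_a) & seed_members
    seeds_b = clustering.members(cluster_b) & seed_members
    rows = []
    for v in sorted(net.nodes()):
        counts = {
            t: (_count_links(net, v, seeds_a, t), _count_links(net, v, seeds_b, t))
            for t in (tau, 0.7, 0.9)
        }
        a, b = counts[tau]
        rows.append(
            SwitchRow(
                node=v,
                conn_a=a,
                conn_b=b,
                switch_score=min(a, b),
                conn_a_07=counts[0.7][0],
                conn_b_07=counts[0.7][1],
                conn_a_09=counts[0.9][0],
                conn_b_09=counts[0.9][1],
            )
        )
    ranked = sorted(
        rows, key=lambda r: (-r.switch_score, -(r.conn_a + r.conn_b), r.node)
    )
    return SwitchReport(
        rows=tuple(ranked),
        top_switches=tuple(r.node for r in ranked[:top_k]),
        threshold=tau,
    )
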
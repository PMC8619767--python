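"""Independent brute-force oracles used to cross-check the library.

Everything here is deliberately naive — explicit BFS, literal path
enumeration, integer-combinatorics sums — and shares no code with the
implementation under test.
"""

from __future__ import annotations

import itertools
import math
from collections import deque


def bfs_distances(adj: dict, source) -> dict:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def graph_adj(net) -> dict:
    return {v: sorted(net.adj[v]) for v in net.nodes()}


def components(adj: dict) -> list[set]:
    seen, comps = set(), []
    for v in adj:
        if v in seen:
            continue
        comp = set(bfs_distances(adj, v))
        seen |= comp
        comps.append(comp)
    return comps


def brute_topology(net) -> dict:
    """Degree/density/clustering/distance statistics by direct enumeration."""
    adj = graph_adj(net)
    nodes = sorted(adj)
    n = len(nodes)
    m = sum(len(adj[v]) for v in nodes) // 2
    deg = {v: len(adj[v]) for v in nodes}

    # local clustering by counting neighbor pairs that are edges
    clustering = []
    for v in nodes:
        nbrs = adj[v]
        if len(nbrs) < 2:
            clustering.append(0.0)
            continue
        links = sum(
            1 for a, b in itertools.combinations(nbrs, 2) if b in adj[a]
        )
        clustering.append(2.0 * links / (len(nbrs) * (len(nbrs) - 1)))

    comps = components(adj)
    giant = max(comps, key=lambda c: (len(c), min(c)))
    ecc = {}
    pair_dists = []
    for v in sorted(giant):
        dist = bfs_distances(adj, v)
        ecc[v] = max(dist[u] for u in giant)
        pair_dists.extend(dist[u] for u in giant if u != v)
    if len(giant) >= 2:
        diameter = max(ecc.values())
        radius = min(ecc.values())
        cpl = sum(pair_dists) / len(pair_dists)
    else:
        diameter = radius = 0
        cpl = 0.0

    mean_deg = sum(deg.values()) / n
    var = sum((d - mean_deg) ** 2 for d in deg.values()) / n
    return {
        "n_nodes": n,
        "n_edges": m,
        "avg_degree": 2.0 * m / n,
        "density": 2.0 * m / (n * (n - 1)),
        "avg_local_clustering": sum(clustering) / n,
        "diameter": diameter,
        "radius": radius,
        "char_path_length": cpl,
        "heterogeneity": 0.0 if mean_deg == 0 else math.sqrt(var) / mean_deg,
        "n_components": len(comps),
        "degree": deg,
    }


def _all_shortest_paths(adj: dict, s, t) -> list[list]:
    dist = bfs_distances(adj, s)
    if t not in dist:
        return []
    paths = []

    def walk(v, path):
        if v == s:
            paths.append(list(reversed(path)))
            return
        for u in adj[v]:
            if dist.get(u, -1) == dist[v] - 1:
                walk(u, path + [u])

    walk(t, [t])
    return paths


def brute_betweenness(net) -> dict:
    """Betweenness by literal enumeration of every shortest path."""
    adj = graph_adj(net)
    nodes = sorted(adj)
    n = len(nodes)
    score = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = _all_shortest_paths(adj, s, t)
        if not paths:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            score[v] += through / len(paths)
    norm = (n - 1) * (n - 2) / 2.0
    return {v: x / norm for v, x in score.items()}


def hypergeom_tail_exact(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) from integer draw counts (exact rational, then float)."""
    numer = sum(
        math.comb(K, i) * math.comb(N - K, n - i)
        for i in range(k, min(n, K) + 1)
        if n - i <= N - K
    )
    return numer / math.comb(N, n)


def bh_fdr_hand(p: list[float]) -> list[float]:
    """Step-up BH computed with explicit sorting and running minimum."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = m - rank_from_end
        running = min(running, p[idx] * m / rank)
        adjusted[idx] = min(running, 1.0)
    return adjusted
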
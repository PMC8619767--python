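"""Construction of the analysis networks from a scored background.

Three steps mirror the usual seed-expansion workflow: confidence filtering
at a minimum required interaction score (default 0.400, inclusive),
zero-order induction on the seeds alone, and first-order expansion that
adds a fixed budget of the seeds' top-ranked direct interactors (default
50 in the first shell, none in the second).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx

from .io import SeedSet

log = logging.getLogger(__name__)

__all__ = ["BuildParams", "filter_by_confidence", "zero_order", "first_order_expand"]


@dataclass(frozen=True)
class BuildParams:
    """Network-construction parameters.

    tau
        Minimum required interaction confidence, inclusive, on [0, 1].
    k_first_shell
        Number of non-seed interactors added in the first shell.
    k_second_shell
        Second-shell budget; only 0 is supported (matching the analysis
        this package reproduces, which adds none in the second shell).
    """

    tau: float = 0.400
    k_first_shell: int = 50
    k_second_shell: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.tau <= 1.0:
            raise ValueError(f"tau {self.tau} outside [0, 1]")
        if self.k_first_shell < 0 or self.k_second_shell < 0:
            raise ValueError("shell budgets must be non-negative")


def filter_by_confidence(net: nx.Graph, tau: float) -> nx.Graph:
    """Keep edges with confidence >= tau; the node set is unchanged."""
    if not 0.0 <= tau <= 1.0:
        raise ValueError(f"tau {tau} outside [0, 1]")
    out = nx.Graph()
    out.add_nodes_from(net.nodes())
    out.add_edges_from(
        (a, b, {"confidence": d["confidence"]})
        for a, b, d in net.edges(data=True)
        if d["confidence"] >= tau
    )
    return out


def zero_order(background: nx.Graph, seeds: SeedSet) -> nx.Graph:
    """Induced subgraph on the seed members (seed proteins only).

    Seeds absent from the background are retained as isolated nodes so the
    seed set never silently shrinks.
    """
    members = set(seeds.members)
    missing = members - set(background.nodes())
    if missing:
        log.info("%d seed(s) absent from background kept as isolated: %s",
                 len(missing), ", ".join(sorted(missing)))
    out = nx.Graph(background.subgraph(members & set(background.nodes())))
    out.add_nodes_from(members)
    return out


def first_order_expand(
    background: nx.Graph, seeds: SeedSet, params: BuildParams = BuildParams()
) -> nx.Graph:
    """Seeds plus the top ``k_first_shell`` ranked non-seed interactors.

    The background is expected to be confidence-filtered already.  Candidate
    non-seed nodes are ranked by (1) number of distinct seed neighbors,
    descending; (2) summed confidence over seed-incident edges, descending;
    (3) identifier, ascending — a deterministic total order.  The result is
    the induced subgraph on seeds plus the selected interactors (absent
    seeds kept isolated).
    """
    if params.k_second_shell != 0:
        raise NotImplementedError("second-shell expansion is not supported")
    members = set(seeds.members)
    scores: dict[str, tuple[int, float]] = {}
    for s in members & set(background.nodes()):
        for nbr, d in background.adj[s].items():
            if nbr in members:
                continue
            cnt, tot = scores.get(nbr, (0, 0.0))
            scores[nbr] = (cnt + 1, tot + d["confidence"])
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1][0], -kv[1][1], kv[0]))
    selected = {node for node, _ in ranked[: params.k_first_shell]}
    keep = (members | selected) & set(background.nodes())
    out = nx.Graph(background.subgraph(keep))
    out.add_nodes_from(members)
    return out
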
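"""Synthetic benchmark generator with ground-truth labels.

Emulates the structure the stroke analysis assumes: a two-community
weighted interaction network (think immune vs. hemostasis), with designated
seed nodes in each community, planted bridge nodes wired to seeds on both
sides (the "switches"), and gene-set collections with terms planted on one
community plus uniform decoys.  Every stage of the pipeline is testable
offline against the returned truth labels.

Defaults mirror the benchmark conditions used throughout the test suite:
two blocks of 20 nodes, intra-block edge probability 0.30, inter-block
0.02, intra-block confidences U(0.60, 0.99), inter-block U(0.40, 0.70),
10 seeds per block, and 2 bridges with 3 seed links per block at
confidence >= 0.7.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .io import GeneSetCollection, GeneSetTerm, SeedSet

__all__ = ["SyntheticSpec", "SyntheticTruth", "generate_network", "generate_genesets"]


@dataclass(frozen=True)
class SyntheticSpec:
    block_sizes: tuple[int, int] = (20, 20)
    p_in: float = 0.30
    p_out: float = 0.02
    conf_in: tuple[float, float] = (0.60, 0.99)
    conf_out: tuple[float, float] = (0.40, 0.70)
    n_seeds_per_block: int = 10
    n_bridges: int = 2
    bridge_links_per_block: int = 3
    bridge_conf_min: float = 0.7
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_out < self.p_in <= 1.0:
            raise ValueError("need 0 <= p_out < p_in <= 1")
        for lo, hi in (self.conf_in, self.conf_out):
            if not 0.0 <= lo <= hi <= 1.0:
                raise ValueError("confidence ranges must lie within [0, 1]")
        if self.n_seeds_per_block > min(self.block_sizes):
            raise ValueError("more seeds than block nodes")
        if self.bridge_links_per_block > self.n_seeds_per_block:
            raise ValueError("bridge_links_per_block exceeds n_seeds_per_block")
        if not 0.0 <= self.bridge_conf_min <= 1.0:
            raise ValueError("bridge_conf_min outside [0, 1]")


@dataclass(frozen=True)
class SyntheticTruth:
    block_of: dict[str, int]
    seed_sets: tuple[SeedSet, SeedSet]
    bridges: tuple[str, ...]
    planted_terms: tuple[str, ...] = ()


def _block_nodes(spec: SyntheticSpec) -> tuple[list[str], list[str]]:
    n1, n2 = spec.block_sizes
    width = len(str(max(n1, n2)))
    b1 = [f"B1N{i + 1:0{width}d}" for i in range(n1)]
    b2 = [f"B2N{i + 1:0{width}d}" for i in range(n2)]
    return b1, b2


def generate_network(spec: SyntheticSpec) -> tuple[nx.Graph, SyntheticTruth]:
    """Draw a planted two-community network with bridge nodes.

    Intra-block node pairs are edges independently with probability
    ``p_in`` (confidence uniform on ``conf_in``); inter-block pairs with
    probability ``p_out`` (confidence uniform on ``conf_out``).  The first
    ``n_seeds_per_block`` nodes of each block are its seeds.  Each bridge
    node is wired to exactly ``bridge_links_per_block`` distinct seeds in
    each block with confidence uniform on [bridge_conf_min, 1).  Fully
    reproducible from ``rng_seed``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    b1, b2 = _block_nodes(spec)
    net = nx.Graph()
    net.add_nodes_from(b1 + b2)

    def wire(nodes_a, nodes_b, p, conf_range, same_block):
        lo, hi = conf_range
        for i, u in enumerate(nodes_a):
            partners = nodes_a[i + 1 :] if same_block else nodes_b
            for v in partners:
                if rng.random() < p:
                    net.add_edge(u, v, confidence=float(rng.uniform(lo, hi)))

    wire(b1, b1, spec.p_in, spec.conf_in, same_block=True)
    wire(b2, b2, spec.p_in, spec.conf_in, same_block=True)
    wire(b1, b2, spec.p_out, spec.conf_out, same_block=False)

    seeds1 = b1[: spec.n_seeds_per_block]
    seeds2 = b2[: spec.n_seeds_per_block]
    bridges = []
    for j in range(spec.n_bridges):
        br = f"BR{j + 1:02d}"
        bridges.append(br)
        net.add_node(br)
        for pool in (seeds1, seeds2):
            chosen = rng.choice(len(pool), size=spec.bridge_links_per_block, replace=False)
            for idx in sorted(int(c) for c in chosen):
                conf = float(rng.uniform(spec.bridge_conf_min, 1.0))
                net.add_edge(br, pool[idx], confidence=min(conf, 0.999))

    truth = SyntheticTruth(
        block_of={**{v: 1 for v in b1}, **{v: 2 for v in b2}},
        seed_sets=(
            SeedSet(name="block1_seeds", members=tuple(seeds1), community="immune"),
            SeedSet(name="block2_seeds", members=tuple(seeds2), community="hemostasis"),
        ),
        bridges=tuple(bridges),
    )
    return net, truth


def combined_seed_set(truth: SyntheticTruth, name: str = "all_seeds") -> SeedSet:
    """Union of both blocks' seed sets, block-1 seeds first."""
    members = truth.seed_sets[0].members + truth.seed_sets[1].members
    return SeedSet(name=name, members=members)


def generate_genesets(
    truth: SyntheticTruth,
    n_planted: int = 3,
    n_decoy: int = 50,
    term_size: int = 25,
    purity: float = 0.8,
    universe_size: int = 5000,
    rng_seed: int = 0,
) -> tuple[GeneSetCollection, SyntheticTruth]:
    """Emit a gene-set collection with terms planted on block 1 plus decoys.

    Each planted term draws ceil(purity x term_size) members from block-1
    nodes and the rest from filler identifiers; decoys draw uniformly from
    the whole universe (network nodes padded with filler identifiers up to
    ``universe_size``).  Returns the collection and a truth updated with the
    planted term ids.
    """
    if not 0.5 < purity <= 1.0:
        raise ValueError("purity must be in (0.5, 1]")
    block1 = sorted(v for v, b in truth.block_of.items() if b == 1)
    network_nodes = sorted(truth.block_of) + list(truth.bridges)
    n_filler = universe_size - len(network_nodes)
    if n_filler < 0:
        raise ValueError("universe_size smaller than the network")
    filler = [f"G{i + 1:06d}" for i in range(n_filler)]
    universe = network_nodes + filler

    n_core = math.ceil(purity * term_size)
    if n_core > len(block1) or term_size > universe_size:
        raise ValueError("infeasible term sizes for the given blocks/universe")

    rng = np.random.default_rng(rng_seed)
    terms: list[GeneSetTerm] = []
    planted_ids = []
    for j in range(n_planted):
        core = rng.choice(len(block1), size=n_core, replace=False)
        pad = rng.choice(len(filler), size=term_size - n_core, replace=False)
        genes = frozenset(
            [block1[int(i)] for i in core] + [filler[int(i)] for i in pad]
        )
        tid = f"PLANTED{j + 1:02d}"
        planted_ids.append(tid)
        terms.append(GeneSetTerm(tid, f"planted block-1 term {j + 1}", genes))
    for j in range(n_decoy):
        picks = rng.choice(len(universe), size=term_size, replace=False)
        genes = frozenset(universe[int(i)] for i in picks)
        terms.append(GeneSetTerm(f"DECOY{j + 1:03d}", f"uniform decoy term {j + 1}", genes))

    collection = GeneSetCollection(
        source_name="synthetic",
        terms=tuple(terms),
        universe_size=universe_size,
        universe=frozenset(universe),
    )
    new_truth = SyntheticTruth(
        block_of=truth.block_of,
        seed_sets=truth.seed_sets,
        bridges=truth.bridges,
        planted_terms=tuple(planted_ids),
    )
    return collection, new_truth
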
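import sys
from pathlib import Path

import networkx as nx
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from ppinet import new_network


@pytest.fixture
def path_abc() -> nx.Graph:
    """The 3-node path A-B-C."""
    return new_network([("A", "B", 0.5), ("B", "C", 0.5)])


@pytest.fixture
def two_triangles() -> nx.Graph:
    """Two triangles joined by a single 0.4-confidence edge."""
    return new_network(
        [
            ("A", "B", 0.9), ("B", "C", 0.9), ("A", "C", 0.9),
            ("D", "E", 0.9), ("E", "F", 0.9), ("D", "F", 0.9),
            ("C", "D", 0.4),
        ]
    )


def random_conf_graph(rng, n: int, p: float) -> nx.Graph:
    """Erdos-Renyi graph with uniform confidences, plus all nodes present."""
    names = [f"N{i:02d}" for i in range(n)]
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges.append((names[i], names[j], round(rng.uniform(0.05, 1.0), 3)))
    return new_network(edges, nodes=names)
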
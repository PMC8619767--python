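"""Detect dense molecular complexes with MCODE.

Two planted cliques with pendant nodes: the vertex weighting ranks clique
members highest, greedy expansion collects each clique, and the haircut
strips the pendants.
"""

import itertools

from ppinet import mcode_complexes, mcode_weights, new_network

clique = lambda names: [(a, b, 0.9) for a, b in itertools.combinations(names, 2)]
edges = clique(["C1", "C2", "C3", "C4", "C5"]) + clique(["D1", "D2", "D3", "D4"])
edges += [("C1", "P1", 0.9), ("D1", "P2", 0.9)]  # pendants
net = new_network(edges)

weights = mcode_weights(net)
print("vertex weights (k-core number x core density of the closed neighborhood):")
for v in sorted(weights, key=weights.get, reverse=True):
    print(f"  {v}: {weights[v]:.3f}")

for i, cx in enumerate(mcode_complexes(net), start=1):
    print(f"complex {i}: {{{', '.join(sorted(cx.members))}}} "
          f"score={cx.score:.2f} (density x size), seeded at {cx.seed_node}")
print("Pendant nodes P1/P2 are cut away: with a single intra-complex link "
      "they cannot belong to a dense core.")
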
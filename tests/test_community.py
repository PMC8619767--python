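"""Markov clustering behavior and switch detection."""

import random
import statistics

import numpy as np
import pytest

from ppinet import Clustering, MCLParams, SeedSet, find_switches, mcl, new_network
from ppinet.synthetic import SyntheticSpec, combined_seed_set, generate_network


def complete_graph(names, conf=0.9):
    return new_network(
        [(a, b, conf) for i, a in enumerate(names) for b in names[i + 1 :]]
    )


def test_single_clique_is_one_cluster():
    c = mcl(complete_graph("ABCD"))
    assert c.n_clusters == 1
    assert set(c.assignment.values()) == {1}


def test_bridged_triangles_split_at_inflation_three(two_triangles):
    c = mcl(two_triangles, MCLParams(inflation=3.0))
    assert c.n_clusters == 2
    assert {c.assignment[v] for v in "ABC"} != {c.assignment[v] for v in "DEF"}
    assert len({c.assignment[v] for v in "ABC"}) == 1


def test_bridged_triangles_match_fixed_point_oracle(two_triangles):
    """Direct high-precision iteration of the stated matrix recurrence,
    without pruning, must produce the same partition."""
    nodes = sorted(two_triangles.nodes())
    idx = {v: i for i, v in enumerate(nodes)}
    A = np.zeros((6, 6))
    for a, b, d in two_triangles.edges(data=True):
        A[idx[a], idx[b]] = A[idx[b], idx[a]] = d["confidence"]
    np.fill_diagonal(A, A.max(axis=0))
    M = A / A.sum(axis=0)
    for _ in range(300):
        M = M @ M
        M = M ** 3.0
        M = M / M.sum(axis=0)
    reachable = (M > 1e-9) | (M > 1e-9).T
    # component of A in the limit structure, by hand BFS
    frontier, comp = {idx["A"]}, {idx["A"]}
    while frontier:
        nxt = {
            j for i in frontier for j in range(6)
            if reachable[i, j] and j not in comp
        }
        comp |= nxt
        frontier = nxt
    assert {nodes[j] for j in comp} == {"A", "B", "C"}
    c = mcl(two_triangles, MCLParams(inflation=3.0))
    assert {v for v in nodes if c.assignment[v] == c.assignment["A"]} == {"A", "B", "C"}


def test_disconnected_components_never_merge():
    net = new_network(
        [("A", "B", 0.9), ("B", "C", 0.9), ("X", "Y", 0.9), ("Y", "Z", 0.9)]
    )
    c = mcl(net)
    assert c.n_clusters >= 2
    assert c.assignment["A"] != c.assignment["X"]


def test_cluster_ids_ordered_by_size_then_member():
    net = new_network(
        [("A", "B", 0.9), ("B", "C", 0.9), ("A", "C", 0.9), ("X", "Y", 0.9)]
    )
    c = mcl(net)
    assert c.assignment["A"] == 1  # triangle is the larger cluster
    assert c.assignment["X"] == 2


def test_mcl_deterministic():
    net, _ = generate_network(SyntheticSpec(rng_seed=4))
    a = mcl(net, MCLParams(inflation=2.0)).assignment
    b = mcl(net, MCLParams(inflation=2.0)).assignment
    assert a == b


def test_median_cluster_count_nondecreasing_in_inflation():
    counts = {infl: [] for infl in (1.5, 2.0, 3.0, 4.0)}
    for s in range(10):
        net, _ = generate_network(SyntheticSpec(rng_seed=s))
        for infl in counts:
            counts[infl].append(mcl(net, MCLParams(inflation=infl)).n_clusters)
    medians = [statistics.median(counts[i]) for i in sorted(counts)]
    assert medians == sorted(medians)


def _truth_clustering(truth):
    assignment = dict(truth.block_of)
    for br in truth.bridges:
        assignment[br] = 1
    return Clustering(
        assignment=assignment, n_clusters=2, converged=True, iterations=0
    )


def test_switch_score_is_min_of_per_cluster_counts():
    net = new_network(
        [("V", "A1", 0.9), ("V", "A2", 0.9), ("V", "A3", 0.9),
         ("V", "B1", 0.9), ("V", "B2", 0.9),
         ("W", "A1", 0.9), ("W", "A2", 0.9), ("W", "B1", 0.9), ("W", "B2", 0.9)]
    )
    clustering = Clustering(
        assignment={"A1": 1, "A2": 1, "A3": 1, "B1": 2, "B2": 2, "V": 1, "W": 2},
        n_clusters=2, converged=True, iterations=0,
    )
    seeds = SeedSet("s", ("A1", "A2", "A3", "B1", "B2"))
    report = find_switches(net, clustering, seeds, 1, 2, tau=0.4, top_k=1)
    by_node = {r.node: r for r in report.rows}
    assert (by_node["V"].conn_a, by_node["V"].conn_b) == (3, 2)
    assert by_node["V"].switch_score == 2
    assert by_node["W"].switch_score == 2
    # tie on score 2 broken by total connections: V has 5, W has 4
    assert report.top_switches == ("V",)


def test_one_sided_node_scores_zero():
    net = new_network([("V", "A1", 0.9), ("V", "A2", 0.9)])
    clustering = Clustering(
        assignment={"A1": 1, "A2": 1, "V": 1, "B1": 2}, n_clusters=2,
        converged=True, iterations=0,
    )
    seeds = SeedSet("s", ("A1", "A2", "B1"))
    report = find_switches(net, clustering, seeds, 1, 2, tau=0.4, top_k=1)
    assert all(r.switch_score == 0 for r in report.rows)


def test_switch_threshold_is_strict():
    net = new_network([("V", "A1", 0.4), ("V", "B1", 0.9)])
    clustering = Clustering(
        assignment={"A1": 1, "B1": 2, "V": 1}, n_clusters=2,
        converged=True, iterations=0,
    )
    seeds = SeedSet("s", ("A1", "B1"))
    report = find_switches(net, clustering, seeds, 1, 2, tau=0.4, top_k=1)
    by_node = {r.node: r for r in report.rows}
    assert by_node["V"].conn_a == 0  # 0.4 is not > 0.4


def test_switch_invariant_to_cluster_label_swap():
    net, truth = generate_network(SyntheticSpec(rng_seed=2))
    clustering = _truth_clustering(truth)
    seeds = combined_seed_set(truth)
    fwd = find_switches(net, clustering, seeds, 1, 2, top_k=3)
    rev = find_switches(net, clustering, seeds, 2, 1, top_k=3)
    assert fwd.top_switches == rev.top_switches
    assert [r.switch_score for r in fwd.rows] == [r.switch_score for r in rev.rows]


def test_switch_tau_one_scores_zero():
    net, truth = generate_network(SyntheticSpec(rng_seed=2))
    clustering = _truth_clustering(truth)
    report = find_switches(net, clustering, combined_seed_set(truth), 1, 2,
                           tau=1.0, top_k=2)
    assert all(r.switch_score == 0 for r in report.rows)


def test_planted_bridges_rank_top():
    net, truth = generate_network(SyntheticSpec(rng_seed=3))
    report = find_switches(
        net, _truth_clustering(truth), combined_seed_set(truth),
        1, 2, tau=0.4, top_k=len(truth.bridges),
    )
    assert set(report.top_switches) == set(truth.bridges)


def test_switch_unknown_cluster_errors():
    net, truth = generate_network(SyntheticSpec(rng_seed=2))
    with pytest.raises(ValueError):
        find_switches(net, _truth_clustering(truth), combined_seed_set(truth), 1, 9)
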
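"""Hypergeometric ORA, BH-FDR, and kappa term clustering."""

import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppinet import (
    GeneSetCollection,
    GeneSetTerm,
    bh_fdr,
    cohens_kappa,
    hypergeom_tail,
    kappa_term_clusters,
    ora,
)
from oracles import bh_fdr_hand, hypergeom_tail_exact


def test_hypergeom_examples():
    assert hypergeom_tail(0, 5, 5, 20) == 1.0
    assert hypergeom_tail(3, 5, 5, 20) == pytest.approx(1126 / 15504, rel=1e-12)
    assert hypergeom_tail(2, 2, 2, 4) == pytest.approx(1 / 6, rel=1e-12)


def test_hypergeom_rejects_bad_margins():
    for bad in [(3, 2, 5, 20), (1, 5, 25, 20), (1, 25, 5, 20), (-1, 5, 5, 20)]:
        with pytest.raises(ValueError):
            hypergeom_tail(*bad)


def test_hypergeom_matches_enumeration_small_sweep():
    rng = random.Random(0)
    for _ in range(300):
        N = rng.randint(1, 25)
        K = rng.randint(0, N)
        n = rng.randint(0, N)
        k = rng.randint(0, min(n, K))
        assert hypergeom_tail(k, n, K, N) == pytest.approx(
            hypergeom_tail_exact(k, n, K, N), rel=1e-12
        )


def test_hypergeom_agrees_with_scipy():
    from scipy.stats import hypergeom

    for k, n, K, N in [(3, 5, 5, 20), (10, 40, 60, 500), (1, 3, 3, 10)]:
        assert hypergeom_tail(k, n, K, N) == pytest.approx(
            float(hypergeom.sf(k - 1, N, K, n)), rel=1e-10
        )


def test_bh_fdr_hand_vectors():
    assert bh_fdr([0.2]) == [pytest.approx(0.2)]
    assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
    assert bh_fdr([0.5, 0.9]) == pytest.approx([0.9, 0.9])
    assert bh_fdr([]) == []
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.2])


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=12))
def test_bh_fdr_properties(pvals):
    q = bh_fdr(pvals)
    assert q == pytest.approx(bh_fdr_hand(pvals), abs=1e-12)
    assert all(qi >= pi - 1e-15 for qi, pi in zip(q, pvals))
    # order invariance up to the induced permutation
    rev = bh_fdr(pvals[::-1])
    assert rev[::-1] == pytest.approx(q, abs=1e-12)


def _collection(terms, universe_size, universe=None):
    return GeneSetCollection(
        "test",
        tuple(GeneSetTerm(t, t.lower(), frozenset(g)) for t, g in terms),
        universe_size,
        frozenset(universe) if universe else None,
    )


def test_ora_direct_count_example():
    genes = [f"G{i}" for i in range(10)]
    coll = _collection([("T1", genes[:5])], universe_size=10)
    rows = ora(genes[:5], coll, min_overlap=1)
    assert rows[0].k_overlap == 5
    assert rows[0].p == pytest.approx(1 / math.comb(10, 5), rel=1e-12)


def test_ora_whole_universe_query_fold_one():
    genes = [f"G{i}" for i in range(12)]
    coll = _collection([("T1", genes[:4]), ("T2", genes[4:9])], universe_size=12)
    rows = ora(genes, coll, min_overlap=1)
    assert all(r.fold == pytest.approx(1.0) for r in rows)


def test_ora_printed_fold_arithmetic():
    """Overlap 42 of a 267-gene query with a 238-gene term in a 20000-gene
    universe gives fold enrichment 13.22 (2 dp)."""
    term = [f"T{i}" for i in range(238)]
    query = term[:42] + [f"Q{i}" for i in range(225)]
    coll = _collection([("DISEASE", term)], universe_size=20000)
    rows = ora(query, coll, min_overlap=1)
    r = rows[0]
    assert (r.k_overlap, r.n_query, r.K_term) == (42, 267, 238)
    assert round(r.fold, 2) == 13.22
    assert r.strength == pytest.approx(math.log10(r.fold))
    assert r.ratio == pytest.approx(238 / 20000)


def test_ora_fold_ratio_identity_and_universe_monotonicity():
    genes = [f"G{i}" for i in range(30)]
    coll_small = _collection([("T1", genes[:10])], universe_size=100)
    coll_big = _collection([("T1", genes[:10])], universe_size=1000)
    q = genes[:8]
    r_small = ora(q, coll_small, min_overlap=3)[0]
    r_big = ora(q, coll_big, min_overlap=3)[0]
    for r in (r_small, r_big):
        assert r.fold == pytest.approx((r.k_overlap / r.n_query) / r.ratio, rel=1e-12)
    assert r_big.p <= r_small.p  # enlarging the universe never increases p


def test_ora_universe_filtering_and_fdr_family():
    genes = [f"G{i}" for i in range(20)]
    coll = _collection(
        [("T1", genes[:6]), ("T2", genes[6:12])],
        universe_size=20,
        universe=genes,
    )
    rows = ora(genes[:6] + ["NOT_IN_UNIVERSE"], coll, min_overlap=3)
    assert rows[0].n_query == 6  # out-of-universe gene dropped
    assert all(r.fdr >= r.p for r in rows)
    with pytest.raises(ValueError):
        ora(["NOT_IN_UNIVERSE"], coll)


def test_kappa_hand_values():
    assert cohens_kappa([1, 1, 0, 0], [1, 1, 0, 0]) == 1.0
    assert cohens_kappa([1, 1, 0, 0], [0, 0, 1, 1]) == pytest.approx(-1.0)
    assert cohens_kappa([1, 1, 1, 1], [1, 1, 1, 1]) == 1.0
    assert cohens_kappa([1, 1, 1, 1], [0, 0, 0, 0]) == 0.0


def test_kappa_agrees_with_sklearn():
    from sklearn.metrics import cohen_kappa_score

    rng = random.Random(8)
    for _ in range(20):
        x = [rng.random() < 0.5 for _ in range(12)]
        y = [rng.random() < 0.5 for _ in range(12)]
        if len(set(x)) < 2 or len(set(y)) < 2:
            continue  # sklearn's degenerate conventions differ
        assert cohens_kappa(x, y) == pytest.approx(
            cohen_kappa_score([int(v) for v in x], [int(v) for v in y]), abs=1e-12
        )


def test_kappa_term_clusters():
    genes = [f"G{i}" for i in range(8)]
    coll = _collection(
        [
            ("T1", genes[:4]),          # identical overlap as T2
            ("T2", genes[:4]),
            ("T3", genes[4:8]),         # disjoint membership
        ],
        universe_size=100,
    )
    rows = ora(genes, coll, min_overlap=1)
    clusters = kappa_term_clusters(rows, genes, threshold=0.3)
    grouped = {frozenset(c.member_terms) for c in clusters}
    assert grouped == {frozenset({"T1", "T2"}), frozenset({"T3"})}
    joint = next(c for c in clusters if "T1" in c.member_terms)
    assert joint.representative in {"T1", "T2"}


def test_kappa_threshold_boundary_is_inclusive():
    # engineered pair with kappa just below/above the threshold
    x = [1, 1, 1, 0, 0, 0, 0, 0]
    y = [1, 1, 0, 1, 0, 0, 0, 0]
    kappa = cohens_kappa(x, y)
    coll = _collection(
        [("TX", [f"G{i}" for i in range(8) if x[i]]),
         ("TY", [f"G{i}" for i in range(8) if y[i]])],
        universe_size=100,
    )
    rows = ora([f"G{i}" for i in range(8)], coll, min_overlap=1)
    below = kappa_term_clusters(rows, [f"G{i}" for i in range(8)],
                                threshold=kappa + 1e-9)
    at = kappa_term_clusters(rows, [f"G{i}" for i in range(8)],
                             threshold=kappa)
    assert len(below) == 2
    assert len(at) == 1
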
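"""Over-representation analysis (ORA) against GMT gene-set collections.

The test statistic is the accumulative (upper-tail) hypergeometric
probability of a query list's overlap with each term, corrected across the
emitted rows of a collection by Benjamini-Hochberg FDR.  Each row also
carries fold enrichment (k/n)/(K/N), its base-10 logarithm ("strength"),
and the term ratio K/N.  Enriched terms can be grouped into clusters of
redundant terms whose gene memberships agree (Cohen's kappa over the query,
single linkage at a threshold, conventionally 0.3).
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection, canonical

log = logging.getLogger(__name__)

__all__ = [
    "EnrichmentRow",
    "TermCluster",
    "hypergeom_tail",
    "bh_fdr",
    "ora",
    "kappa_term_clusters",
    "cohens_kappa",
]


@dataclass(frozen=True)
class EnrichmentRow:
    """One term's over-representation statistics.

    k_overlap / n_query / K_term / N_universe are the classical 2x2 margins:
    overlap, effective query size, term size, and universe size.
    """

    term_id: str
    description: str
    k_overlap: int
    n_query: int
    K_term: int
    N_universe: int
    ratio: float
    p: float
    fdr: float
    fold: float
    strength: float
    overlap_genes: tuple[str, ...]


@dataclass(frozen=True)
class TermCluster:
    member_terms: tuple[str, ...]
    representative: str
    kappa_threshold: float


def _log_comb(a, b):
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), in log space.

    N is the universe size, K the term size, n the query size, k the
    observed overlap.  Exact log-binomials summed with logsumexp; k = 0
    returns exactly 1.
    """
    if not (0 <= k <= min(n, K) and 0 <= n <= N and 0 <= K <= N):
        raise ValueError(f"invalid hypergeometric margins k={k} n={n} K={K} N={N}")
    if k == 0:
        return 1.0
    i = np.arange(k, min(n, K) + 1)
    log_terms = _log_comb(K, i) + _log_comb(N - K, n - i) - _log_comb(N, n)
    return float(min(1.0, math.exp(logsumexp(log_terms))))


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return [float(q) for q in multipletests(p, method="fdr_bh")[1]]


def _effective_query(query: Sequence[str], collection: GeneSetCollection) -> list[str]:
    seen: set[str] = set()
    effective: list[str] = []
    for g in query:
        ident = canonical(g)
        if ident in seen:
            continue
        seen.add(ident)
        if collection.universe is not None and ident not in collection.universe:
            log.warning("query gene %s outside the declared universe, dropped", ident)
            continue
        effective.append(ident)
    return effective


def ora(
    query: Sequence[str],
    collection: GeneSetCollection,
    min_overlap: int = 3,
) -> list[EnrichmentRow]:
    """Over-representation of a query list against every term of a collection.

    Terms overlapping the effective query (unique, in-universe genes) by at
    least ``min_overlap`` are tested; FDR is adjusted over exactly the
    emitted rows.  Rows are sorted by p ascending, ties by fold descending,
    then term_id.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    effective = _effective_query(query, collection)
    if not effective:
        raise ValueError("query is empty after universe filtering")
    n = len(effective)
    N = collection.universe_size
    qset = set(effective)
    rows: list[EnrichmentRow] = []
    pvals: list[float] = []
    for term in collection.terms:
        overlap = sorted(term.genes & qset)
        k = len(overlap)
        if k < min_overlap:
            continue
        K = len(term.genes)
        p = hypergeom_tail(k, n, K, N)
        fold = (k / n) / (K / N)
        rows.append(
            EnrichmentRow(
                term_id=term.term_id,
                description=term.description,
                k_overlap=k,
                n_query=n,
                K_term=K,
                N_universe=N,
                ratio=K / N,
                p=p,
                fdr=math.nan,  # filled below over the emitted family
                fold=fold,
                strength=math.log10(fold),
                overlap_genes=tuple(overlap),
            )
        )
        pvals.append(p)
    if not rows:
        return []
    fdrs = bh_fdr(pvals)
    rows = [dataclasses.replace(row, fdr=q) for row, q in zip(rows, fdrs)]
    rows.sort(key=lambda r: (r.p, -r.fold, r.term_id))
    return rows


def cohens_kappa(x: Sequence[bool], y: Sequence[bool]) -> float:
    """Cohen's kappa between two binary vectors of equal length.

    Degenerate case: when chance agreement is 1 (both vectors constant),
    kappa is 1 for identical vectors and 0 otherwise.
    """
    x = np.asarray(x, dtype=bool)
    y = np.asarray(y, dtype=bool)
    if x.shape != y.shape:
        raise ValueError("membership vectors differ in length")
    m = x.size
    a = int(np.sum(x & y))
    b = int(np.sum(x & ~y))
    c = int(np.sum(~x & y))
    d = int(np.sum(~x & ~y))
    po = (a + d) / m
    pe = ((a + b) * (a + c) + (c + d) * (b + d)) / (m * m)
    if pe == 1.0:
        return 1.0 if po == 1.0 else 0.0
    return (po - pe) / (1.0 - pe)


def kappa_term_clusters(
    rows: Sequence[EnrichmentRow],
    query: Sequence[str],
    threshold: float = 0.3,
) -> list[TermCluster]:
    """Group enriched terms whose query memberships agree (kappa >= threshold).

    Each term is represented as a binary membership vector over the query;
    single-linkage connected components at kappa >= threshold form the
    clusters.  Each cluster's representative is its lowest-p member (ties
    broken by smaller term_id).  Clusters are returned by representative p
    ascending.
    """
    if not rows:
        raise ValueError("no enrichment rows to cluster")
    if not -1.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (-1, 1]")
    genes = []
    seen: set[str] = set()
    for g in query:
        ident = canonical(g)
        if ident not in seen:
            seen.add(ident)
            genes.append(ident)
    vectors = {
        row.term_id: np.array([g in row.overlap_genes for g in genes]) for row in rows
    }
    ids = [row.term_id for row in rows]
    parent = {t: t for t in ids}

    def find(t):
        while parent[t] != t:
            parent[t] = parent[parent[t]]
            t = parent[t]
        return t

    for i, t1 in enumerate(ids):
        for t2 in ids[i + 1 :]:
            if cohens_kappa(vectors[t1], vectors[t2]) >= threshold:
                parent[find(t2)] = find(t1)

    by_root: dict[str, list[EnrichmentRow]] = {}
    for row in rows:
        by_root.setdefault(find(row.term_id), []).append(row)
    clusters = []
    for members in by_root.values():
        rep = min(members, key=lambda r: (r.p, r.term_id))
        clusters.append(
            TermCluster(
                member_terms=tuple(sorted(r.term_id for r in members)),
                representative=rep.term_id,
                kappa_threshold=threshold,
            )
        )
    rep_p = {row.term_id: row.p for row in rows}
    clusters.sort(key=lambda c: (rep_p[c.representative], c.representative))
    return clusters
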
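"""Scoring a query gene set against every network in a collection.

Three measures of alignment are computed per candidate network, each
highlighting a different aspect of the match:

similarity
    Cosine similarity between the query and the network, both encoded
    as binary gene vectors weighted by inverse document frequency,
    ``idf(g) = ln(m / df(g))``. A gene found in every network (df = m)
    weighs zero; rare shared genes dominate the score.

p-value
    The hypergeometric upper tail P(X >= k): the probability of drawing
    at least the observed overlap ``k`` when sampling ``n`` query genes
    from a universe of ``N`` genes of which ``K`` lie in the network.
    Raw p-values are Benjamini–Hochberg adjusted across the whole
    collection: each p is multiplied by the number of networks queried
    (``m``, counting zero-overlap networks that are never returned) and
    divided by its ascending rank, followed by the standard step-up
    monotonicity pass and a cap at 1.

overlap
    The plain count of genes present in both the query and the network.

Sorting by any key is stable, so chained sorts compose: sorting by
p-value and then by overlap yields an overlap-major, p-value-minor
ordering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

from scipy.stats import hypergeom

from .index import CollectionIndex, candidate_networks
from .symbols import (
    DEFAULT_QUERY_WARN_LIMIT,
    NormalizationResult,
    SymbolTable,
    normalize_query,
)

__all__ = [
    "ScoredResult",
    "QueryResult",
    "SORT_KEYS",
    "overlap_count",
    "idf",
    "tfidf_weights",
    "cosine_similarity",
    "hypergeom_ccdf",
    "bh_adjust",
    "rank_results",
    "run_query",
]

SORT_KEYS = ("similarity", "pvalue", "overlap")


@dataclass
class ScoredResult:
    set_id: str
    name: str
    K: int  # genes in the network (success states in the population)
    k: int  # observed overlap with the query
    similarity: float
    p_raw: float
    pvalue_rank: int  # ascending BH rank of p_raw among candidates
    p_adj: float
    overlapping_genes: list[str]  # sorted


@dataclass
class QueryResult:
    results: list[ScoredResult]
    n: int  # effective query size used in the hypergeometric test
    sort_key: str
    normalization: NormalizationResult


# ---------------------------------------------------------------------------
# the three metrics
# ---------------------------------------------------------------------------


def overlap_count(query: set[str], network_genes: frozenset[str] | set[str]) -> int:
    """Number of genes in both the query set and the network."""
    return len(query & network_genes)


def idf(index: CollectionIndex, gene: str) -> float:
    """Inverse document frequency ln(m / df) of a universe gene.

    Strictly decreasing in df; zero for a gene present in every
    network. Raises :class:`KeyError` for genes outside the universe
    (their df is undefined).
    """
    return math.log(index.m / index.df[gene])


def tfidf_weights(index: CollectionIndex, genes: set[str]) -> dict[str, float]:
    """Binary-TF IDF weight vector over ``genes ∩ universe``."""
    return {g: idf(index, g) for g in genes if g in index.df}


def cosine_similarity(
    query: set[str],
    network_genes: frozenset[str] | set[str],
    index: CollectionIndex,
) -> float:
    """Cosine of the IDF-weighted binary vectors of the two sets.

    Both sets are restricted to the index universe. Returns 0.0 when
    either vector has zero norm (empty after restriction, or made only
    of ubiquitous zero-weight genes); the result is clipped to [0, 1]
    against rounding.
    """
    qw = tfidf_weights(index, set(query))
    dw = tfidf_weights(index, set(network_genes))
    q_norm_sq = sum(w * w for w in qw.values())
    d_norm_sq = sum(w * w for w in dw.values())
    if q_norm_sq == 0.0 or d_norm_sq == 0.0:
        return 0.0
    dot = sum(qw[g] * dw[g] for g in qw.keys() & dw.keys())
    return min(1.0, dot / math.sqrt(q_norm_sq * d_norm_sq))


def hypergeom_ccdf(N: int, K: int, n: int, k: int) -> float:
    """Upper tail P(X >= k) of Hypergeometric(N, K, n).

    Arguments follow the urn convention: ``N`` population size, ``K``
    success states, ``n`` sample size, ``k`` observed successes. The
    result lies in (0, 1]; P(X >= 0) = 1 exactly. Invalid arguments
    raise :class:`ValueError`.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid urn: N={N}, K={K}, n={n}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"k={k} outside [0, min(K={K}, n={n})]")
    if k == 0:
        return 1.0
    p = float(hypergeom.sf(k - 1, N, K, n))
    if p <= 0.0:
        # double-precision underflow in the tail sum; fall back to exact
        # rational enumeration and return the nearest representable float
        p = float(_hypergeom_ccdf_exact(N, K, n, k))
        if p == 0.0:
            p = 5e-324  # smallest positive float, keeps p_raw in (0, 1]
    return min(1.0, p)


def _hypergeom_ccdf_exact(N: int, K: int, n: int, k: int) -> Fraction:
    total = math.comb(N, n)
    upper = sum(
        math.comb(K, i) * math.comb(N - K, n - i) for i in range(k, min(K, n) + 1)
    )
    return Fraction(upper, total)


def bh_adjust(p_raw: list[float], m: int) -> list[float]:
    """Benjamini–Hochberg adjustment with explicit multiplicity ``m``.

    ``m`` is the number of networks queried and may exceed ``len(p_raw)``
    because zero-overlap networks count toward the multiplicity without
    producing a result. Sorted ascending, ``adj_r = p_r * m / r``; a
    right-to-left cumulative minimum restores monotonicity and values
    are capped at 1. Output is returned in the input order.
    """
    if not p_raw:
        return []
    if m < len(p_raw):
        raise ValueError(f"m={m} smaller than the number of p-values {len(p_raw)}")
    order = sorted(range(len(p_raw)), key=lambda i: p_raw[i])  # stable
    adj_sorted = [p_raw[i] * m / (rank + 1) for rank, i in enumerate(order)]
    for r in range(len(adj_sorted) - 2, -1, -1):
        adj_sorted[r] = min(adj_sorted[r], adj_sorted[r + 1])
    out = [0.0] * len(p_raw)
    for rank, i in enumerate(order):
        out[i] = min(1.0, adj_sorted[rank])
    return out


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------

_KEY_FUNCS = {
    "similarity": lambda r: -r.similarity,
    "pvalue": lambda r: r.p_adj,
    "overlap": lambda r: -r.k,
}


def rank_results(results: list[ScoredResult], sort_key: str) -> list[ScoredResult]:
    """Order results by one key; ties keep their incoming order.

    ``similarity`` and ``overlap`` sort descending, ``pvalue`` sorts
    ascending on the adjusted p-value. Stability is part of the
    contract: re-sorting an already sorted list by a second key yields
    the composed ordering.
    """
    try:
        key = _KEY_FUNCS[sort_key]
    except KeyError:
        raise ValueError(
            f"unknown sort key {sort_key!r}; expected one of {SORT_KEYS}"
        ) from None
    return sorted(results, key=key)


def run_query(
    raw_query: str,
    index: CollectionIndex,
    table: SymbolTable,
    sort_key: str = "similarity",
    max_results: int | None = None,
    query_warn_limit: int = DEFAULT_QUERY_WARN_LIMIT,
) -> QueryResult:
    """The full scoring pipeline for one query.

    Steps: normalize the query → intersect with the index universe
    (fixing the sample size ``n``) → prune to candidate networks with
    overlap >= 1 → score each candidate (k, K, similarity, raw p) →
    BH-adjust across the collection → stable-rank by ``sort_key`` →
    truncate to ``max_results``.

    A query with no gene in the universe yields an empty result list
    (the normalization report still explains every token); it is not an
    error.
    """
    if sort_key not in SORT_KEYS:
        raise ValueError(
            f"unknown sort key {sort_key!r}; expected one of {SORT_KEYS}"
        )
    norm = normalize_query(raw_query, table, warn_limit=query_warn_limit)
    effective = {g for g in norm.effective_query if g in index.universe}
    n = len(effective)
    if n == 0:
        return QueryResult(results=[], n=0, sort_key=sort_key, normalization=norm)

    candidates = candidate_networks(index, effective)
    results: list[ScoredResult] = []
    for set_id in candidates:
        gs = index.networks[set_id]
        shared = sorted(effective & gs.genes)
        results.append(
            ScoredResult(
                set_id=set_id,
                name=gs.name,
                K=len(gs.genes),
                k=len(shared),
                similarity=cosine_similarity(effective, gs.genes, index),
                p_raw=hypergeom_ccdf(index.N, len(gs.genes), n, len(shared)),
                pvalue_rank=0,  # assigned below
                p_adj=0.0,
                overlapping_genes=shared,
            )
        )

    p_raw = [r.p_raw for r in results]
    p_adj = bh_adjust(p_raw, m=index.m)
    order = sorted(range(len(results)), key=lambda i: p_raw[i])
    for rank, i in enumerate(order, start=1):
        results[i].pvalue_rank = rank
        results[i].p_adj = p_adj[i]

    ranked = rank_results(results, sort_key)
    if max_results is not None:
        ranked = ranked[:max_results]
    return QueryResult(results=ranked, n=n, sort_key=sort_key, normalization=norm)
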
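"""Hypergeometric enrichment statistics for gene clusters and gene sets.

Notation follows the usual over-representation setup: a background of M
annotated genes of which K carry the annotation of interest, and a query
set of N annotated genes of which X carry it.  Then

    fold        = (X/N) / (K/M)
    p_enriched  = P(>= X successes)  = 1 - sum_{i<X}  C(K,i) C(M-K,N-i) / C(M,N)
    p_depleted  = P(<= X successes)  =     sum_{i<=X} C(K,i) C(M-K,N-i) / C(M,N)

computed exactly in log-space (log-gamma terms, compensated summation) so
backgrounds of tens of thousands of genes do not overflow.  Fold > 1
routes to the enrichment tail, otherwise to the depletion tail.  Multiple
testing is controlled by Benjamini–Hochberg across all (cluster, term)
tests jointly.

Cluster quality is summarized as the percentage of annotated genes having
at least one of their own annotations enriched in their own cluster.

``empirical_permutation_p`` is the generic add-one permutation p-value
(r + 1)/(n + 1) for r of n randomized replicates meeting or exceeding the
observed statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp, fsum, lgamma
from typing import Iterable, Mapping, Sequence

from .fusion import Clustering


@dataclass
class EnrichmentResult:
    term: str
    set_id: str
    X: int
    N: int
    K: int
    M: int
    fold: float
    p_raw: float
    p_adjusted: float | None
    direction: str  # "enriched" or "depleted"


def _check_bounds(x: int, n: int, k: int, m: int) -> None:
    if not (0 <= k <= m and 0 < n <= m):
        raise ValueError(f"invalid background: N={n}, K={k}, M={m}")
    if not (0 <= x <= min(n, k)):
        raise ValueError(f"invalid count X={x} for N={n}, K={k}")


def _log_comb(n: int, k: int) -> float:
    return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)


def _hypergeom_pmf_terms(n: int, k: int, m: int, lo: int, hi: int) -> list[float]:
    log_denom = _log_comb(m, n)
    out = []
    for i in range(lo, hi + 1):
        if n - i > m - k:
            out.append(0.0)
            continue
        out.append(exp(_log_comb(k, i) + _log_comb(m - k, n - i) - log_denom))
    return out


def hypergeom_enrichment_p(x: int, n: int, k: int, m: int) -> float:
    """Upper-tail hypergeometric probability P(>= X); X = 0 gives 1."""
    _check_bounds(x, n, k, m)
    if x == 0:
        return 1.0
    upper = min(n, k)
    p = fsum(_hypergeom_pmf_terms(n, k, m, x, upper))
    return min(1.0, max(p, 0.0))


def depletion_p(x: int, n: int, k: int, m: int) -> float:
    """Lower-tail hypergeometric probability P(<= X)."""
    _check_bounds(x, n, k, m)
    p = fsum(_hypergeom_pmf_terms(n, k, m, 0, x))
    return min(1.0, max(p, 0.0))


def fold_enrichment(x: int, n: int, k: int, m: int) -> float:
    """(X/N) / (K/M); requires N > 0 and K > 0."""
    if n <= 0 or k <= 0:
        raise ValueError("fold enrichment needs N > 0 and K > 0")
    _check_bounds(x, n, k, m)
    return (x / n) / (k / m)


def bh_adjust(pvals: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, order-preserving."""
    for p in pvals:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"p-value {p} outside [0, 1]")
    n = len(pvals)
    if n == 0:
        return []
    order = sorted(range(n), key=lambda i: pvals[i])
    adjusted = [0.0] * n
    running_min = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, pvals[i] * n / rank)
        adjusted[i] = running_min
    return adjusted


def gene_set_stats(
    gene_set: Iterable[str],
    background: Iterable[str],
    markers: Iterable[str],
    set_id: str = "set",
    term: str = "markers",
) -> EnrichmentResult:
    """Enrichment/depletion of marker genes in a gene set vs a background.

    The set must be contained in the background and the markers must
    intersect it (K = 0 leaves fold undefined).  Direction is decided by
    the fold: > 1 tests the enrichment tail, otherwise the depletion tail.
    """
    gene_set = set(gene_set)
    background = set(background)
    markers = set(markers)
    if not gene_set <= background:
        extra = sorted(gene_set - background)[:3]
        raise ValueError(f"gene set not contained in background (e.g. {extra})")
    k = len(markers & background)
    if k == 0:
        raise ValueError("no marker gene intersects the background (K = 0)")
    m = len(background)
    n = len(gene_set)
    x = len(markers & gene_set)
    fold = fold_enrichment(x, n, k, m)
    if fold > 1.0:
        direction = "enriched"
        p = hypergeom_enrichment_p(x, n, k, m)
    else:
        direction = "depleted"
        p = depletion_p(x, n, k, m)
    return EnrichmentResult(
        term=term, set_id=set_id, X=x, N=n, K=k, M=m,
        fold=fold, p_raw=p, p_adjusted=None, direction=direction,
    )


def cluster_enrichment(
    clustering: Clustering,
    annotations: Mapping[str, Iterable[str]],
    alpha: float = 0.05,
) -> tuple[list[EnrichmentResult], float]:
    """Per-cluster annotation enrichment and the cluster-quality percentage.

    Only annotated genes count toward the cluster sizes N and the
    background M.  Every (cluster, term) pair with at least one annotated
    member is tested with the enrichment tail; BH correction is applied
    jointly across all tests.  A term is enriched in a cluster iff its
    adjusted p <= alpha.  The returned percentage is the share of
    annotated genes having at least one of their own annotations enriched
    in their own cluster.
    """
    terms = {t: set(gs) for t, gs in annotations.items()}
    annotated: set[str] = set()
    universe = set(clustering.assignment)
    for gs in terms.values():
        annotated |= gs & universe
    if not annotated:
        raise ValueError("no annotated gene appears in the clustering")
    m = len(annotated)
    gene_terms: dict[str, set[str]] = {g: set() for g in annotated}
    for t, gs in terms.items():
        for g in gs & annotated:
            gene_terms[g].add(t)

    clusters = clustering.clusters()
    results: list[EnrichmentResult] = []
    for cid in sorted(clusters):
        members = clusters[cid] & annotated
        n = len(members)
        if n == 0:
            continue
        for t in sorted(terms):
            k = len(terms[t] & annotated)
            if k == 0:
                continue
            x = len(terms[t] & members)
            results.append(
                EnrichmentResult(
                    term=t, set_id=str(cid), X=x, N=n, K=k, M=m,
                    fold=(x / n) / (k / m),
                    p_raw=hypergeom_enrichment_p(x, n, k, m),
                    p_adjusted=None, direction="enriched",
                )
            )
    adjusted = bh_adjust([r.p_raw for r in results])
    for r, p_adj in zip(results, adjusted):
        r.p_adjusted = p_adj

    enriched_terms: dict[str, set[str]] = {}  # cluster id -> enriched terms
    for r in results:
        if r.p_adjusted is not None and r.p_adjusted <= alpha:
            enriched_terms.setdefault(r.set_id, set()).add(r.term)
    covered = 0
    for g in annotated:
        cid = str(clustering.assignment[g])
        if gene_terms[g] & enriched_terms.get(cid, set()):
            covered += 1
    percent_covered = 100.0 * covered / m
    return results, percent_covered


def empirical_permutation_p(r: int, n: int) -> float:
    """Add-one empirical p-value (r + 1)/(n + 1) from n randomized
    replicates of which r met or exceeded the observed statistic."""
    if n < 1:
        raise ValueError("need at least one replicate")
    if not (0 <= r <= n):
        raise ValueError("exceed count r must satisfy 0 <= r <= n")
    return (r + 1) / (n + 1)
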
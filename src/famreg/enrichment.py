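"""Hypergeometric over-representation test with Benjamini-Hochberg FDR."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    k: int  # targets annotated with the term
    K: int  # background genes annotated with the term
    n: int  # target-set size
    N: int  # background size
    p: float
    q: float

    @property
    def significant(self) -> bool:
        return self.q < 0.05


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= n <= N and 0 <= K <= N):
        raise ValueError(f"invalid hypergeometric bounds k={k} K={K} n={n} N={N}")
    if k > K:
        return 0.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotone non-decreasing q along the sorted order
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def enrich(
    target_set: set[str],
    annotation: dict[str, set[str]],
    background: set[str],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Over-representation of every annotated term in the target set.

    ``annotation`` maps gene -> set of terms; only background genes count.
    Results are sorted by (q, p, term); ``significant`` means q < alpha
    (exposed via the 0.05-fixed property; use alpha to filter yourself).
    """
    if not background:
        raise ValueError("empty background gene set")
    extra = target_set - background
    if extra:
        raise ValueError(f"target genes outside background: {sorted(extra)[:5]}")
    N = len(background)
    n = len(target_set)
    term_background: dict[str, int] = {}
    term_targets: dict[str, int] = {}
    for gene in background:
        for term in annotation.get(gene, ()):
            term_background[term] = term_background.get(term, 0) + 1
            if gene in target_set:
                term_targets[term] = term_targets.get(term, 0) + 1
    terms = sorted(term_background)
    pvals = [
        hypergeom_upper(term_targets.get(t, 0), term_background[t], n, N)
        for t in terms
    ]
    qvals = bh_fdr(pvals)
    results = [
        EnrichmentResult(
            term=t,
            k=term_targets.get(t, 0),
            K=term_background[t],
            n=n,
            N=N,
            p=pvals[i],
            q=float(qvals[i]),
        )
        for i, t in enumerate(terms)
    ]
    results.sort(key=lambda r: (r.q, r.p, r.term))
    return results
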
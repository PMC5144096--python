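"""Hypergeometric over-representation analysis with permutation specificity.

Standard gene-set over-representation: for a query of n genes drawn from a
background of N, a term annotating K background genes with k of them in the
query is scored with the upper-tail hypergeometric probability P(X >= k),
then Benjamini-Hochberg adjusted across all tested terms.  Term specificity
is assessed the way enrichment robustness is usually probed: R random query
sets of the same size are drawn from a gene pool and the frequency with
which each observed term re-enriches is reported, together with an add-one
empirical p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "AnnotationSet",
    "EnrichmentResult",
    "TermSpecificity",
    "read_gmt",
    "hypergeom_p",
    "bh_adjust",
    "enrich",
    "permutation_specificity",
]


@dataclass(frozen=True)
class AnnotationSet:
    """Term -> gene-set map restricted to a background universe."""

    terms: dict[str, frozenset[str]]
    background: frozenset[str]

    def restricted(self, universe: Iterable[str]) -> "AnnotationSet":
        """Restrict background and terms to ``universe``; drop emptied terms."""
        bg = frozenset(self.background & set(universe))
        terms = {
            t: genes & bg for t, genes in self.terms.items() if genes & bg
        }
        return AnnotationSet({t: frozenset(g) for t, g in terms.items()}, bg)


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    k: int  # overlap of query and term
    K: int  # term size in background
    n: int  # query size
    N: int  # background size
    p: float
    p_adj: float


@dataclass(frozen=True)
class TermSpecificity:
    term: str
    perm_count: int
    n_permutations: int

    @property
    def perm_frequency(self) -> float:
        return self.perm_count / self.n_permutations

    @property
    def empirical_p(self) -> float:
        return (self.perm_count + 1) / (self.n_permutations + 1)


def read_gmt(path: str | Path) -> AnnotationSet:
    """Read a GMT file (term, description, member genes...).

    The background is the union of all member genes; callers typically
    restrict it to their analysis universe via
    :meth:`AnnotationSet.restricted`.
    """
    terms: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected term, desc, genes")
            term, _desc, *genes = fields
            if term in terms:
                raise ValueError(f"{path}: line {lineno}: duplicate term {term!r}")
            terms[term] = frozenset(g for g in genes if g)
    if not terms:
        raise ValueError(f"{path}: no gene sets found")
    background = frozenset().union(*terms.values())
    return AnnotationSet(terms, background)


def hypergeom_p(N: int, K: int, n: int, k: int, ease: bool = False) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts annotated genes in a size-n draw without replacement from N
    genes of which K are annotated.  ``ease=True`` applies the DAVID-style
    conservative variant scoring P(X >= k-1 | k >= 1) by discounting one
    overlapping gene.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts N={N}, K={K}, n={n}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"k={k} outside [0, min(K={K}, n={n})]")
    if ease and k > 0:
        k = k - 1
    if k == 0:
        return 1.0
    # survival function at k-1 gives P(X >= k); scipy evaluates in log space
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m == 0:
        return []
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adj
    return out.tolist()


def enrich(
    query: Iterable[str],
    ann: AnnotationSet,
    alpha: float = 0.05,
    min_overlap: int = 1,
    ease: bool = False,
) -> list[EnrichmentResult]:
    """Over-representation of every annotation term in ``query``.

    Query genes outside the background are dropped.  Only terms overlapping
    the query by at least ``min_overlap`` genes are tested (zero-overlap
    terms are uninformative and would only inflate the BH denominator);
    BH adjustment runs across all tested terms.  Results are sorted by
    (p, term).
    """
    qset = frozenset(query) & ann.background
    N = len(ann.background)
    n = len(qset)
    tested: list[tuple[str, int, int, float]] = []
    for term in sorted(ann.terms):
        genes = ann.terms[term]
        k = len(genes & qset)
        if k < min_overlap:
            continue
        K = len(genes)
        tested.append((term, k, K, hypergeom_p(N, K, n, k, ease=ease)))
    padj = bh_adjust([t[3] for t in tested])
    results = [
        EnrichmentResult(term, k, K, n, N, p, pa)
        for (term, k, K, p), pa in zip(tested, padj)
    ]
    results.sort(key=lambda r: (r.p, r.term))
    return results


def significant_terms(results: Sequence[EnrichmentResult], alpha: float = 0.05) -> list[str]:
    return [r.term for r in results if r.p_adj < alpha]


def permutation_specificity(
    observed_terms: Sequence[str],
    ann: AnnotationSet,
    pool: Iterable[str],
    m: int,
    n_permutations: int = 100,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
    ease: bool = False,
) -> list[TermSpecificity]:
    """How often each observed term enriches in random same-size queries.

    Draws ``n_permutations`` query sets of size ``m`` uniformly without
    replacement from ``pool``, runs the full enrichment on each, and counts
    per observed term the permutations in which it reaches p_adj < alpha.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    pool = sorted(set(pool))
    if m > len(pool):
        raise ValueError(f"query size m={m} exceeds pool size {len(pool)}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    counts = {t: 0 for t in observed_terms}
    for _ in range(n_permutations):
        perm_query = rng.choice(pool, size=m, replace=False)
        hits = set(significant_terms(enrich(perm_query, ann, alpha, ease=ease), alpha))
        for t in counts:
            if t in hits:
                counts[t] += 1
    return [TermSpecificity(t, c, n_permutations) for t, c in counts.items()]


def results_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.term, r.k, r.K, r.n, r.N, r.p, r.p_adj) for r in results],
        columns=["term", "k", "K", "n", "N", "p", "p_adj"],
    )


def specificity_frame(spec: Sequence[TermSpecificity]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (s.term, s.perm_count, s.n_permutations, s.perm_frequency, s.empirical_p)
            for s in spec
        ],
        columns=["term", "perm_count", "n_permutations", "perm_frequency", "empirical_p"],
    )
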
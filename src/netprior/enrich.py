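"""Gene-set over-representation analysis with kappa-score term grouping.

A drop-in replacement for a ClueGO-style enrichment step: each annotation
term overlapping the query is tested with a right-tailed hypergeometric test
against a finite background, p-values are corrected for multiple testing
(Holm step-down by default, mirroring ClueGO), and significant terms are
grouped by chance-corrected agreement (Cohen's kappa) of their gene
memberships, single-linkage at a kappa threshold (0.4 by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .graph_core import AnnotationSet

_METHODS = {
    "holm": "holm",
    "bonferroni": "bonferroni",
    "benjamini-hochberg": "fdr_bh",
    "bh": "fdr_bh",
}


@dataclass
class EnrichmentTerm:
    """Result of testing one annotated term against the query."""

    term_id: str
    name: str
    K: int          # annotated genes in background
    k: int          # overlap with query
    n: int          # query size (restricted to background)
    N: int          # background size
    p_raw: float
    p_adj: float = 1.0
    significant: bool = False
    group: int | None = None


def hypergeom_pvalue(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), evaluated in log space.

    ``N`` background size, ``K`` term size, ``n`` query size, ``k`` overlap.
    """
    if not (0 <= k <= min(K, n) and k <= K <= N and 0 <= n <= N):
        raise ValueError(
            f"inconsistent counts: k={k}, n={n}, K={K}, N={N}"
        )
    if k == 0:
        return 1.0
    # sf(k-1) = P(X >= k); scipy evaluates the tail stably in log space
    logp = stats.hypergeom.logsf(k - 1, N, K, n)
    return float(min(1.0, np.exp(logp)))


def adjust_pvalues(pvalues, method: str = "holm") -> list[float]:
    """Multiple-testing adjustment preserving input order.

    Methods: ``holm`` (step-down FWER), ``bonferroni``, ``benjamini-hochberg``
    (step-up FDR).  Outputs are monotone in the appropriate sense and clipped
    at 1.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    key = method.lower()
    if key not in _METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {sorted(_METHODS)}")
    _, p_adj, _, _ = multipletests(p, alpha=0.05, method=_METHODS[key])
    return [float(x) for x in p_adj]


def enrich(
    query,
    ann: AnnotationSet,
    alpha: float = 0.01,
    method: str = "holm",
) -> list[EnrichmentTerm]:
    """Test every annotation term with query overlap >= 1.

    Results are sorted by adjusted p-value, ties by term id.  Query genes
    outside the background are dropped with a warning.
    """
    if not ann.terms:
        raise ValueError("empty annotation set")
    query = frozenset(query)
    in_bg = query & ann.background
    if not in_bg:
        warnings.warn("query has no genes in the annotation background", stacklevel=2)
        return []
    if in_bg != query:
        warnings.warn(
            f"{len(query - in_bg)} query gene(s) outside the background were dropped",
            stacklevel=2,
        )
    N = len(ann.background)
    n = len(in_bg)
    results: list[EnrichmentTerm] = []
    for tid in sorted(ann.terms):
        name, genes = ann.terms[tid]
        k = len(genes & in_bg)
        if k == 0:
            continue
        p = hypergeom_pvalue(k, n, len(genes), N)
        results.append(EnrichmentTerm(tid, name, len(genes), k, n, N, p_raw=p))
    if not results:
        return []
    adj = adjust_pvalues([t.p_raw for t in results], method=method)
    for t, pa in zip(results, adj):
        t.p_adj = pa
        t.significant = pa <= alpha
    results.sort(key=lambda t: (t.p_adj, t.term_id))
    return results


def cohens_kappa(a: int, b: int, c: int, d: int) -> float:
    """Cohen's kappa from 2x2 agreement counts.

    ``a`` both-member, ``b``/``c`` one-member, ``d`` neither-member counts of
    two gene sets over a common background of size a+b+c+d.
    """
    total = a + b + c + d
    if total == 0:
        raise ValueError("empty contingency table")
    po = (a + d) / total
    pe = ((a + b) * (a + c) + (c + d) * (b + d)) / total**2
    if pe == 1.0:
        return 1.0 if po == 1.0 else 0.0
    return (po - pe) / (1.0 - pe)


def kappa_group(
    terms: list[EnrichmentTerm],
    ann: AnnotationSet,
    threshold: float = 0.4,
) -> dict[str, int]:
    """Single-linkage grouping of significant terms by membership kappa.

    Terms whose pairwise Cohen's kappa over the background reaches
    ``threshold`` are merged; groups are numbered from 0 in order of their
    best (lowest p_adj, then term id) member, which also labels the group.
    Each term's ``group`` field is set; the mapping term id -> group id is
    returned.
    """
    sig = [t for t in terms if t.significant]
    if not sig:
        return {}
    ids = [t.term_id for t in sig]
    members = {t.term_id: ann.terms[t.term_id][1] for t in sig}
    N = len(ann.background)

    parent = {tid: tid for tid in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, t1 in enumerate(ids):
        for t2 in ids[i + 1:]:
            g1, g2 = members[t1], members[t2]
            a = len(g1 & g2)
            b = len(g1 - g2)
            c = len(g2 - g1)
            d = N - a - b - c
            if cohens_kappa(a, b, c, d) >= threshold:
                parent[find(t1)] = find(t2)

    # number groups by their best member (lowest p_adj, then term id)
    order = sorted(sig, key=lambda t: (t.p_adj, t.term_id))
    group_ids: dict[str, int] = {}
    next_id = 0
    for t in order:
        root = find(t.term_id)
        if root not in group_ids:
            group_ids[root] = next_id
            next_id += 1
    assignment = {tid: group_ids[find(tid)] for tid in ids}
    for t in terms:
        t.group = assignment.get(t.term_id)
    return assignment
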
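"""Hypergeometric over-representation analysis and term-coverage comparison.

For a query gene list of size *n* drawn from a universe of size *N*, a
term with *K* members and overlap *k* gets the one-sided upper-tail
probability ``P(X >= k)`` with ``X ~ Hypergeom(N, K, n)``.  Raw p < alpha
is the default significance call; Benjamini–Hochberg adjusted values are
always reported and can drive the call instead.  The universe defaults
to the union of all genes in the collection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .importance import BASELINE_METHODS, extract_eis, node_importance
from .io import GeneSetCollection

__all__ = [
    "EnrichmentResult",
    "hypergeom_pvalue",
    "enrich",
    "term_coverage",
    "compare_importance_methods",
]


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeom(N, K, n), clipped to [0, 1]."""
    return min(1.0, max(0.0, float(hypergeom.sf(k - 1, N, K, n))))

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    """One term's over-representation statistics."""

    term: str
    description: str
    k: int
    K: int
    n: int
    N: int
    p: float
    p_adj: float
    significant: bool


def enrich(
    query: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str] | None = None,
    alpha: float = 0.05,
    significance: Literal["raw", "adjusted"] = "raw",
) -> list[EnrichmentResult]:
    """Test every term in the collection against a query gene list.

    Query genes outside the universe are dropped with a warning.  Set
    membership is intersected with the universe as well, so N, K, n, k
    are all counted in the same space.  Results come back sorted by
    ascending p (ties by term id).
    """
    universe_set = (
        frozenset(universe) if universe is not None else collection.all_genes()
    )
    if not universe_set:
        raise ValueError("empty universe")
    query_set = frozenset(query)
    outside = query_set - universe_set
    if outside:
        log.warning("enrich: dropping %d query genes outside the universe", len(outside))
        query_set &= universe_set
    N, n = len(universe_set), len(query_set)
    raw: list[tuple[str, str, int, int, float]] = []
    for term in sorted(collection.sets):
        desc, members = collection.sets[term]
        members = members & universe_set
        if not members:
            continue
        K = len(members)
        k = len(members & query_set)
        raw.append((term, desc, k, K, hypergeom_pvalue(k, K, n, N)))
    if not raw:
        return []
    _, p_adj, _, _ = multipletests([r[4] for r in raw], method="fdr_bh")
    results = []
    for (term, desc, k, K, p), pa in zip(raw, p_adj):
        sig = (p < alpha) if significance == "raw" else (pa < alpha)
        results.append(
            EnrichmentResult(
                term=term, description=desc, k=k, K=K, n=n, N=N, p=p, p_adj=float(pa),
                significant=sig,
            )
        )
    results.sort(key=lambda r: (r.p, r.term))
    return results


def significant_terms(results: Sequence[EnrichmentResult]) -> frozenset[str]:
    return frozenset(r.term for r in results if r.significant)


def term_coverage(reference: Iterable[str], candidate: Iterable[str]) -> float:
    """|reference ∩ candidate| / |reference|."""
    ref = frozenset(reference)
    if not ref:
        raise ValueError("empty reference term list")
    return len(ref & frozenset(candidate)) / len(ref)


def compare_importance_methods(
    tp_graph: nx.Graph,
    methods: Sequence[str],
    target_genes: Iterable[str],
    pathogenic_genes: Iterable[str],
    collection: GeneSetCollection,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Benchmark IM against baseline centralities by functional coverage.

    The reference is the set of terms significantly enriched in *both*
    the full target list and the pathogenic list (the functional basis
    shared by treatment and disease).  For each scoring method the
    above-median nodes are enriched and their significant terms compared
    to the reference; the table reports coverage per method, best first.
    """
    allowed = {"im", *BASELINE_METHODS}
    bad = set(methods) - allowed
    if bad:
        raise ValueError(f"unknown method(s): {sorted(bad)}; choose from {sorted(allowed)}")
    ref = significant_terms(enrich(target_genes, collection, alpha=alpha)) & \
        significant_terms(enrich(pathogenic_genes, collection, alpha=alpha))
    if not ref:
        raise ValueError("no common reference terms between targets and pathogenic genes")
    table = node_importance(tp_graph, graph_id="tp", with_baselines=True)
    rows = []
    for method in methods:
        scores = table.scores[method]
        med = scores.median()
        kept = [v for v in tp_graph.nodes if scores[v] > med]
        terms = significant_terms(enrich(kept, collection, alpha=alpha)) if kept else set()
        rows.append(
            {
                "method": method,
                "n_kept": len(kept),
                "n_terms": len(terms),
                "coverage": term_coverage(ref, terms),
            }
        )
    df = pd.DataFrame(rows).sort_values(
        ["coverage", "method"], ascending=[False, True], ignore_index=True
    )
    df.attrs["n_reference_terms"] = len(ref)
    return df
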
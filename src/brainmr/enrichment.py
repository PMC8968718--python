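"""Hypergeometric over-representation of a gene set in annotation terms.

For each term, the 2x2 table of (in query) x (in term) over a gene universe
is scored with the one-sided upper-tail hypergeometric p-value, an odds
ratio with 95% Wald interval on the log scale (Haldane-Anscombe 0.5
correction when any cell is zero), and a log-OR z statistic.  q-values are
Benjamini-Hochberg within each ontology — one annotation table is one
family.  The universe is the set of genes measured on the expression
platform, not the whole genome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .multiplicity import bh_fdr
from .simulate import AnnotationTable

__all__ = ["EnrichmentResult", "hypergeom_enrich", "top_terms"]


@dataclass
class EnrichmentResult:
    term_id: str
    name: str
    ontology: str
    k: int  # overlap: query genes annotated to the term
    n: int  # query size (within universe)
    K: int  # term size (within universe)
    N: int  # universe size
    p: float
    q: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    z: float


def _odds_ratio(k: int, n: int, K: int, N: int) -> tuple[float, float, float, float]:
    a, b, c, d = k, n - k, K - k, N - K - n + k
    if min(a, b, c, d) == 0:  # Haldane-Anscombe
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(or_)
    return or_, math.exp(log_or - 1.96 * se), math.exp(log_or + 1.96 * se), log_or / se


def hypergeom_enrich(
    query: list[str] | set[str],
    table: AnnotationTable,
    universe: list[str] | set[str],
) -> list[EnrichmentResult]:
    """Score every term of one annotation table against a query gene set."""
    universe = set(universe)
    query = set(query)
    if not universe:
        raise ValueError("empty gene universe")
    if not query:
        raise ValueError("empty query gene set")
    if not query <= universe:
        raise ValueError(f"query contains genes outside the universe: "
                         f"{sorted(query - universe)[:5]}")
    N, n = len(universe), len(query)
    results = []
    for term in table.terms:
        members = set(term.genes) & universe
        K = len(members)
        if K > N:
            raise ValueError(f"term {term.term_id} larger than universe")
        k = len(members & query)
        p = float(sps.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        p = min(1.0, max(p, np.finfo(float).tiny))
        or_, lo, hi, z = _odds_ratio(k, n, K, N)
        results.append(
            EnrichmentResult(term.term_id, term.name, table.ontology,
                             k, n, K, N, p, 1.0, or_, lo, hi, z)
        )
    qvals = bh_fdr([r.p for r in results]) if results else []
    for r, q in zip(results, qvals):
        r.q = float(q)
    return results


def top_terms(results: list[EnrichmentResult], limit: int = 20) -> list[EnrichmentResult]:
    """Most enriched terms: ascending q, ties by p then term id; truncated."""
    return sorted(results, key=lambda r: (r.q, r.p, r.term_id))[:limit]
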
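"""Local gene-set overrepresentation analysis (Fisher + Benjamini-Hochberg).

Replaces a web enrichment service with a self-contained test against a
user-supplied GMT annotation collection. For each term, a one-sided
Fisher's exact test (upper hypergeometric tail) asks whether the query
hits the term more often than chance given the annotated background;
Benjamini-Hochberg adjustment is applied within each category (CC and BP
separately). The background is the union of all annotated symbols in the
collection, and the query is restricted to it before testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import AnalysisConfig, AnnotationSet

logger = logging.getLogger("keynet")

__all__ = ["EnrichmentRow", "fisher_term_p", "bh_adjust", "enrich", "top_terms"]


@dataclass(frozen=True)
class EnrichmentRow:
    term_id: str
    term_name: str
    category: str
    k: int  # query hits in term
    K: int  # background members of term
    n: int  # query size within background
    N: int  # background size
    fold: float
    p: float
    q: float


def fisher_term_p(k: int, K: int, n: int, N: int) -> float:
    """One-sided enrichment p: hypergeometric upper tail P(X >= k).

    Drawing ``n`` query genes from a background of ``N`` of which ``K``
    belong to the term.
    """
    if not (0 <= k <= K <= N and k <= n <= N):
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    query,
    annotations: AnnotationSet,
    config: AnalysisConfig | None = None,
) -> list[EnrichmentRow]:
    """Term overrepresentation of a query symbol set.

    Returns the rows passing both the raw-p and BH-q thresholds of
    ``config`` (defaults p < 0.01, q < 0.05), sorted ascending by p within
    category (CC before BP), with the full row set filtered after BH
    adjustment within each category.
    """
    cfg = config or AnalysisConfig()
    qset = frozenset(query) & annotations.background
    if not qset:
        raise ValueError(
            "query shares no symbol with the annotation background; "
            "check symbol namespaces"
        )
    n = len(qset)
    N = len(annotations.background)
    out: list[EnrichmentRow] = []
    for category in ("CC", "BP"):
        terms = annotations.by_category(category)
        if not terms:
            continue
        rows = []
        for t in terms:
            k = len(qset & t.members)
            K = len(t.members)
            p = fisher_term_p(k, K, n, N)
            fold = (k / n) / (K / N) if k else 0.0
            rows.append((t, k, K, p, fold))
        qvals = bh_adjust([r[3] for r in rows])
        for (t, k, K, p, fold), q in zip(rows, qvals):
            if p < cfg.enrichment_p_threshold and q < cfg.enrichment_q_threshold:
                out.append(
                    EnrichmentRow(
                        term_id=t.term_id,
                        term_name=t.name,
                        category=category,
                        k=k,
                        K=K,
                        n=n,
                        N=N,
                        fold=fold,
                        p=p,
                        q=float(q),
                    )
                )
    out.sort(key=lambda r: (r.category, r.p, r.term_id))
    logger.info("enrich: %d significant terms for query of %d symbols", len(out), n)
    return out


def top_terms(rows: list[EnrichmentRow], n: int = 5) -> list[EnrichmentRow]:
    """Top-n most significant rows per category (rows assumed sorted by p)."""
    out: list[EnrichmentRow] = []
    for category in ("CC", "BP"):
        cat_rows = [r for r in rows if r.category == category]
        out.extend(sorted(cat_rows, key=lambda r: r.p)[:n])
    return out
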
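"""Gene-set over-representation filter for DE genes.

The DE gene list is reduced to genes participating in significantly
over-represented terms (biological-process style) before network
construction.  Per term the one-sided upper hypergeometric tail
P(X >= k) is computed with population N (background), K successes
(background genes in the term), n draws (query size) and k observed
(query genes in the term).  Selection uses the raw p < alpha by
default; Benjamini-Hochberg adjustment is available via config.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datatypes import TermAnnotation
from .errors import PreconditionError


@dataclass(frozen=True)
class EnrichmentRecord:
    term_id: str
    name: str
    namespace: str
    k: int  # query genes in term
    K: int  # background genes in term
    n: int  # query size
    N: int  # background size
    p: float


def over_representation(
    query: set[str], background: set[str], annotation: TermAnnotation
) -> list[EnrichmentRecord]:
    """One-sided over-representation p per term, sorted by (p, term id).

    Term gene sets are clipped to the background before counting so
    that K and k are consistent with the population.
    """
    if not background:
        raise PreconditionError("background is empty")
    stray = query - background
    if stray:
        raise PreconditionError(f"query genes absent from background: {sorted(stray)}")
    N, n = len(background), len(query)
    records = []
    for term_id, (name, namespace, genes) in annotation.terms.items():
        in_bg = genes & background
        K = len(in_bg)
        if K == 0:
            continue
        k = len(in_bg & query)
        # P(X >= k) for hypergeometric(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        records.append(EnrichmentRecord(term_id, name, namespace, k, K, n, N, min(p, 1.0)))
    records.sort(key=lambda r: (r.p, r.term_id))
    return records


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (monotone step-up)."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p, kind="stable")
    m = p.size
    adj = np.empty(m)
    adj[order] = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    return np.clip(adj, 0.0, 1.0)


def select_genes_in_significant_terms(
    records: list[EnrichmentRecord],
    annotation: TermAnnotation,
    query: set[str],
    alpha: float = 0.05,
    namespace: str | None = "BP",
    adjust: bool = False,
) -> set[str]:
    """Union of query genes in significant terms of one namespace.

    This is the filtered query gene set handed to network construction.
    With ``adjust`` the threshold applies to BH-adjusted p-values.
    """
    if not records:
        return set()
    pvals = np.array([r.p for r in records])
    crit = benjamini_hochberg(pvals) if adjust else pvals
    selected: set[str] = set()
    for rec, pc in zip(records, crit):
        if namespace is not None and rec.namespace != namespace:
            continue
        # strict p < alpha; alpha=1 disables the filter entirely (a term
        # covering the whole background has p exactly 1 and still passes)
        if pc < alpha or alpha >= 1.0:
            selected |= annotation.genes_of(rec.term_id) & query
    return selected
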
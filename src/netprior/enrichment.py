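"""Over-representation testing of a gene list against annotation terms.

Plain upper-tail hypergeometric tests with Benjamini-Hochberg step-up
adjustment.  The background defaults to all genes of the analyzed
network (the pool the ranking draws from), not the genome.  A term is
flagged disease-related when it annotates at least one seed gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.stats import hypergeom


@dataclass
class EnrichmentResult:
    term: str
    k: int  # overlap with the gene list
    n: int  # gene-list size (within background)
    K: int  # term size (within background)
    N: int  # background size
    p_value: float
    adjusted_p: float = float("nan")
    disease_related: bool = False


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    adjusted_(i) = min_{j >= rank(i)} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(adjusted_sorted, 1.0)
    return adjusted


def hypergeometric_enrichment(
    gene_list: Iterable[str],
    term_to_genes: dict[str, Iterable[str]],
    background: Iterable[str],
    skip_empty_overlap: bool = False,
    seeds: Optional[Iterable[str]] = None,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of ``gene_list`` per term.

    Term gene sets are intersected with the background before testing;
    p = P(X >= k | N, K, n).  Terms with zero overlap are reported with
    p = 1 unless ``skip_empty_overlap`` is set.  When ``seeds`` is given,
    terms annotating at least one seed are flagged disease-related.
    Results carry BH-adjusted p-values and are sorted by p-value then term.

    Raises
    ------
    ValueError
        on an empty background or a gene list not contained in it.
    """
    background = set(background)
    if not background:
        raise ValueError("empty background")
    genes = set(gene_list)
    if not genes <= background:
        stray = sorted(genes - background)[:5]
        raise ValueError(f"gene list not contained in background (e.g. {stray})")
    seed_set = set(seeds) if seeds is not None else set()

    N, n = len(background), len(genes)
    results: list[EnrichmentResult] = []
    for term in sorted(term_to_genes):
        term_genes = set(term_to_genes[term]) & background
        K = len(term_genes)
        if K == 0:
            continue
        k = len(term_genes & genes)
        if k == 0 and skip_empty_overlap:
            continue
        p = float(hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        results.append(
            EnrichmentResult(
                term=term, k=k, n=n, K=K, N=N,
                p_value=min(p, 1.0),
                disease_related=bool(term_genes & seed_set),
            )
        )
    if results:
        adjusted = benjamini_hochberg([r.p_value for r in results])
        for r, adj in zip(results, adjusted):
            r.adjusted_p = float(adj)
    results.sort(key=lambda r: (r.p_value, r.term))
    return results


def significant_terms(
    results: Sequence[EnrichmentResult], alpha: float = 0.05
) -> list[EnrichmentResult]:
    """Terms with BH-adjusted p below ``alpha`` (default 0.05)."""
    return [r for r in results if r.adjusted_p < alpha]
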
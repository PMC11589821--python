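"""Term enrichment with the Soybase-style Bonferroni-by-multiplication.

Per term, over/under-representation of the query set against the background
is assessed with one-sided hypergeometric tails; the direction is chosen by
the sign of (observed - expected).  Raw p-values are multiplied — not
clipped — by a configurable multiplier, by default the number of scanned
(query) genes following the Soybase convention (so corrected p-values can
exceed 1); a term is significant when the corrected p is at most 0.01.
A curated flowering/reproduction/senescence/photosynthesis/development
(FRSPD) term list can then be applied, retaining biological-process terms
only.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "EnrichmentResult",
    "fisher_enrichment",
    "filter_frspd",
    "bonferroni_by_multiplication",
]

SIGNIFICANCE_CUTOFF = 0.01
_BP_ALIASES = {"bp", "biological_process", "biological process", "p"}


def bonferroni_by_multiplication(p_raw: float, multiplier: int) -> float:
    """Soybase-style Bonferroni: the raw p-value is multiplied by the number
    of scanned genes and NOT clipped at 1 (e.g. 0.003 x 4000 genes = 12)."""
    return p_raw * multiplier


@dataclass(frozen=True)
class EnrichmentResult:
    """One term's enrichment verdict."""

    term_id: str
    term_name: str
    k: int  # annotated genes in the query set
    K: int  # annotated genes in the background
    n: int  # query size
    N: int  # background size
    direction: str  # "over" | "under"
    p_raw: float
    p_corrected: float  # may exceed 1 by construction
    significant: bool


def fisher_enrichment(
    query_genes: list[str],
    background_genes: list[str],
    annotation: pd.DataFrame,
    multiplier: int | None = None,
    cutoff: float = SIGNIFICANCE_CUTOFF,
) -> list[EnrichmentResult]:
    """Hypergeometric term enrichment of a query set within a background.

    ``annotation`` has columns gene_id, term_id, term_name (category
    optional).  ``multiplier`` defaults to the number of scanned (query)
    genes; pass ``len(terms)`` for a conventional terms-count Bonferroni.
    Results are sorted by corrected p.
    """
    query = set(query_genes)
    background = set(background_genes)
    if not query:
        raise ValueError("query gene set is empty")
    if not query <= background:
        raise ValueError("query genes must be a subset of the background")

    ann = annotation[annotation["gene_id"].isin(background)]
    N = len(background)
    n = len(query)
    mult = n if multiplier is None else multiplier

    results = []
    for (term_id, term_name), sub in ann.groupby(["term_id", "term_name"], sort=True):
        genes = set(sub["gene_id"])
        K = len(genes)
        k = len(genes & query)
        expected = n * K / N
        if k >= expected:
            direction = "over"
            p_raw = float(hypergeom.sf(k - 1, N, K, n))
        else:
            direction = "under"
            p_raw = float(hypergeom.cdf(k, N, K, n))
        p_corr = p_raw * mult
        results.append(
            EnrichmentResult(
                term_id=str(term_id),
                term_name=str(term_name),
                k=k, K=K, n=n, N=N,
                direction=direction,
                p_raw=p_raw,
                p_corrected=p_corr,
                significant=p_corr <= cutoff,
            )
        )
    results.sort(key=lambda r: (r.p_corrected, r.term_id))
    return results


def filter_frspd(
    results: list[EnrichmentResult], frspd_terms: pd.DataFrame
) -> list[EnrichmentResult]:
    """Keep only curated biological-process terms.

    ``frspd_terms`` has columns term_id, category; molecular-function and
    cellular-component entries on the curated list are ignored, so only
    results whose term is a curated biological-process annotation survive.
    """
    if frspd_terms.empty:
        return []
    bp = frspd_terms[
        frspd_terms["category"].astype(str).str.strip().str.lower().isin(_BP_ALIASES)
    ]
    keep = set(bp["term_id"].astype(str))
    return [r for r in results if r.term_id in keep]


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Tabular view of enrichment results."""
    return pd.DataFrame(
        [
            {
                "term_id": r.term_id, "term_name": r.term_name,
                "k": r.k, "K": r.K, "n": r.n, "N": r.N,
                "direction": r.direction, "p_raw": r.p_raw,
                "p_corrected": r.p_corrected, "significant": r.significant,
            }
            for r in results
        ]
    )
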
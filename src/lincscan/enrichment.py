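"""Hypergeometric GO-term enrichment with Bonferroni correction."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats


@dataclass
class EnrichmentResult:
    term_id: str
    k: int  # hits in the gene set
    n: int  # gene-set size
    K: int  # hits in the background
    N: int  # background size
    p: float
    p_bonf: float
    term_name: str = ""


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail probability P(X >= k) for X ~ Hypergeom(N, K, n).

    p = sum_{i=k}^{min(n,K)} C(K,i) C(N-K,n-i) / C(N,n), evaluated via the
    log-space survival function for stability.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(n, K)):
        raise ValueError(f"inconsistent arguments k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def go_enrich(
    gene_set: Iterable[str],
    background: Iterable[str],
    term_map: Mapping[str, set[str]],
    term_names: Mapping[str, str] | None = None,
) -> list[EnrichmentResult]:
    """One hypergeometric test per term with >= 1 hit in the gene set.

    ``term_map`` maps gene -> set of term IDs. Bonferroni multiplies by the
    number of terms actually tested. Results are sorted by (p, term_id).
    """
    genes = set(gene_set)
    bg = set(background)
    stray = sorted(genes - bg)
    if stray:
        raise ValueError(f"genes absent from background: {stray}")
    by_term: dict[str, set[str]] = {}
    for gene in bg:
        for term in term_map.get(gene, ()):
            by_term.setdefault(term, set()).add(gene)
    tested = {
        term: members for term, members in by_term.items() if members & genes
    }
    T = len(tested)
    results = []
    for term, members in tested.items():
        k = len(members & genes)
        K = len(members)
        p = hypergeom_upper(k, K, len(genes), len(bg))
        results.append(
            EnrichmentResult(
                term_id=term,
                k=k,
                n=len(genes),
                K=K,
                N=len(bg),
                p=p,
                p_bonf=min(1.0, p * T),
                term_name=(term_names or {}).get(term, ""),
            )
        )
    results.sort(key=lambda r: (r.p, r.term_id))
    return results


def read_term_map(path) -> dict[str, set[str]]:
    """Two-column TSV (gene, term) -> gene -> set of terms."""
    term_map: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            gene, term = line.rstrip("\n").split("\t")[:2]
            term_map.setdefault(gene, set()).add(term)
    return term_map


def results_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "term_name": r.term_name,
                "k": r.k,
                "n": r.n,
                "K": r.K,
                "N": r.N,
                "p": r.p,
                "p_bonferroni": r.p_bonf,
                "raw_significant": r.p < 0.05,
                "corrected_significant": r.p_bonf < 0.05,
            }
            for r in results
        ]
    )
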
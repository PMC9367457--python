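"""Gene-set (pathway) analysis on top of the gene burden results.

Two complementary views:

* **enrichment** — is a pathway over-represented in the list of genes whose
  burden test came out significant?  Right-tailed Fisher exact test
  (hypergeometric upper tail) of the overlap, against a stated gene universe.
  The universe size is a required parameter: it depends on the knowledge base
  the gene sets come from and changes the p-values materially.
* **carrier odds ratio** — are case individuals over-represented among the
  carriers of at least one qualifying variant in *any* gene of the pathway?
  This reuses the exact 2×2 machinery at carrier level and does not depend on
  a gene universe.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.stats import hypergeom

from .association import ContingencyTable, fisher_two_tailed, odds_ratio_exact
from .burden import GeneBurdenResult
from .cohort_io import CarrierMatrix, GeneSet, VariantKey

__all__ = [
    "PathwayResult",
    "enrichment_fisher_right",
    "significant_gene_list",
    "pathway_carrier_test",
    "run_pathway_analysis",
]


@dataclass(frozen=True)
class PathwayResult:
    name: str
    n_hits: int  # significant genes in the pathway
    pathway_size: int
    enrichment_p: Optional[float]
    case_carriers: int
    case_n: int
    control_carriers: int
    control_n: int
    carrier_or: float
    carrier_ci_low: float
    carrier_ci_high: float
    carrier_p: float


def enrichment_fisher_right(k: int, K: int, n: int, N: int) -> float:
    """Right-tailed Fisher enrichment p-value: P(X >= k).

    ``k`` significant genes fall in a pathway of ``K`` genes, out of ``n``
    significant genes drawn from a universe of ``N``.
    """
    if not (0 <= k <= min(K, n)) or K > N or n > N:
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    return float(hypergeom.sf(k - 1, N, K, n))


def significant_gene_list(
    burden_results: Sequence[GeneBurdenResult], alpha: float = 0.05
) -> list[str]:
    """Genes whose *raw* burden p-value is strictly below ``alpha``."""
    return [r.gene for r in burden_results if r.p_raw < alpha]


def pathway_carrier_test(
    pathway: GeneSet,
    qualifying: Mapping[str, Sequence[VariantKey]],
    genotypes: CarrierMatrix,
    conf_level: float = 0.95,
) -> tuple[ContingencyTable, float, float, float, float]:
    """Carrier-level 2×2 test of a pathway.

    An individual counts once if carrying >= 1 qualifying variant in >= 1
    pathway gene.  Returns (table, OR, ci_low, ci_high, p).  A pathway with
    no qualifying variants in any member gene yields zero carriers and p = 1.
    """
    carrier = np.zeros(genotypes.n_samples, dtype=bool)
    for gene in pathway.genes:
        for key in qualifying.get(gene, ()):
            carrier |= genotypes.carriers(key)
    case_mask = genotypes.case_mask
    a = int((carrier & case_mask).sum())
    c = int((carrier & ~case_mask).sum())
    table = ContingencyTable(
        a, int(case_mask.sum()) - a, c, genotypes.n_samples - int(case_mask.sum()) - c,
        "carrier",
    )
    if a == 0 and c == 0:
        return table, float("nan"), float("nan"), float("nan"), 1.0
    p = fisher_two_tailed(table)
    est, lo, hi = odds_ratio_exact(table, conf_level)
    return table, est, lo, hi, p


def run_pathway_analysis(
    pathways: Sequence[GeneSet],
    burden_results: Sequence[GeneBurdenResult],
    qualifying: Mapping[str, Sequence[VariantKey]],
    genotypes: CarrierMatrix,
    universe_size: int,
    alpha: float = 0.05,
    conf_level: float = 0.95,
) -> list[PathwayResult]:
    """Enrichment and carrier tests for every pathway."""
    sig_genes = set(significant_gene_list(burden_results, alpha))
    n = len(sig_genes)
    results: list[PathwayResult] = []
    for pw in pathways:
        K = len(pw.genes)
        k = len(sig_genes & pw.genes)
        enr = enrichment_fisher_right(k, K, n, universe_size) if universe_size else None
        table, est, lo, hi, p = pathway_carrier_test(pw, qualifying, genotypes, conf_level)
        results.append(
            PathwayResult(
                name=pw.name,
                n_hits=k,
                pathway_size=K,
                enrichment_p=enr,
                case_carriers=table.a,
                case_n=table.case_n,
                control_carriers=table.c,
                control_n=table.control_n,
                carrier_or=est,
                carrier_ci_low=lo,
                carrier_ci_high=hi,
                carrier_p=p,
            )
        )
    return results
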
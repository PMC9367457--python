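"""Gene-level carrier-collapsing burden testing with coverage control.

Each gene's qualifying variants (rare, predicted pathogenic, in the gene —
including singletons) are collapsed to a per-individual carrier indicator:
1 iff the individual carries at least one qualifying variant in the gene.
The resulting carrier-level 2×2 table (case/control × carrier/non-carrier)
is tested with the two-tailed Fisher exact test; the effect size reported is
the log carrier odds ratio with a Haldane–Anscombe 0.5 correction applied
when any cell is zero.  p-values are BH-adjusted across tested genes.

Cohorts sequenced on different platforms differ in coverage, and sites that
are well covered in one cohort only produce spurious carrier-count imbalance.
``depth_filter`` removes variants whose mean depth falls below a per-cohort
cutoff, and ``select_depth_cutoff`` picks the cutoff by balancing test
calibration — the squared correlation of the observed vs expected uniform
quantiles of the burden p-values (QQ R²) — against the number of variants
sacrificed: the smallest cutoff whose R² comes within a tolerance of the best
achievable R² is chosen.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .association import ContingencyTable, bh_adjust, fisher_two_tailed
from .cohort_io import AnnotatedVariant, CarrierMatrix, DepthRecord, VariantKey

logger = logging.getLogger(__name__)

__all__ = [
    "GeneBurdenResult",
    "DepthFilterConfig",
    "collapse_to_carriers",
    "depth_filter",
    "qq_r_squared",
    "select_depth_cutoff",
    "burden_test",
    "run_burden_scan",
]


@dataclass(frozen=True)
class GeneBurdenResult:
    gene: str
    case_carriers: int
    case_n: int
    control_carriers: int
    control_n: int
    p_raw: float
    p_fdr: float
    effect: float  # log carrier odds ratio, Haldane-Anscombe corrected


@dataclass
class DepthFilterConfig:
    """Per-cohort candidate mean-depth cutoffs (reads per sample).

    By default only the control cohort is filtered — the cutoff controls for
    the control cohort's distinct sequencing platform; case-cohort cutoffs can
    be added via ``cutoffs``.  ``selection_tolerance`` is the R² slack used
    when choosing among candidates.
    """

    cutoffs: dict[str, float] = field(default_factory=dict)
    candidate_cutoffs: list[float] = field(default_factory=lambda: [0.0, 25.1])
    selection_tolerance: float = 0.01

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.candidate_cutoffs) or any(
            c < 0 for c in self.cutoffs.values()
        ):
            raise ValueError("depth cutoffs must be >= 0")


def collapse_to_carriers(
    genotypes: CarrierMatrix,
    qualifying: Mapping[str, Sequence[VariantKey]],
) -> dict[str, np.ndarray]:
    """Per-gene boolean carrier indicator over the cohort's individuals.

    ``qualifying`` maps gene -> its qualifying variant keys.  Genes with no
    qualifying variants are omitted (logged).  An individual carrying several
    qualifying variants in a gene still counts once.
    """
    indicators: dict[str, np.ndarray] = {}
    for gene, keys in qualifying.items():
        if not keys:
            logger.info("gene %s has no qualifying variants: omitted from burden", gene)
            continue
        carrier = np.zeros(genotypes.n_samples, dtype=bool)
        for key in keys:
            carrier |= genotypes.carriers(key)
        indicators[gene] = carrier
    return indicators


def depth_filter(
    variants: Sequence[AnnotatedVariant],
    depths: Sequence[DepthRecord],
    cutoffs: Mapping[str, float],
) -> list[AnnotatedVariant]:
    """Keep variants whose mean depth meets the cutoff in every filtered cohort.

    A variant with no depth record for a cohort that has a cutoff is treated
    as depth 0 (removed, with a warning in the log).  Filtering is monotone:
    raising a cutoff can only shrink the retained set.
    """
    if not cutoffs:
        return list(variants)
    table: dict[tuple[VariantKey, str], float] = {
        (r.variant_key, r.cohort_label): r.mean_depth for r in depths
    }
    retained = []
    for v in variants:
        ok = True
        for cohort, cutoff in cutoffs.items():
            depth = table.get((v.key, cohort))
            if depth is None:
                logger.warning(
                    "no %s depth record for %s: treated as depth 0", cohort, v.key
                )
                depth = 0.0
            if depth < cutoff:
                ok = False
                break
        if ok:
            retained.append(v)
    return retained


def qq_r_squared(p_values: Sequence[float]) -> float:
    """Calibration of a p-value set: R² of the observed-vs-expected QQ plot.

    Observed sorted -log10 p-values are correlated against the uniform
    order-statistic quantiles -log10((i - 0.5) / m); the squared Pearson
    correlation is returned.  Requires >= 3 p-values with nonzero variance.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size < 3:
        raise ValueError("qq_r_squared needs at least 3 p-values")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    obs = -np.log10(np.sort(p))
    if np.allclose(obs, obs[0]):
        raise ValueError("constant p-values: QQ correlation undefined")
    m = p.size
    # obs is descending (smallest p first); expected likewise pairs the
    # smallest p with the most extreme uniform quantile (0.5/m)
    expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    r = np.corrcoef(obs, expected)[0, 1]
    return float(r * r)


def burden_test(
    gene: str,
    case_carriers: int,
    case_n: int,
    control_carriers: int,
    control_n: int,
) -> tuple[float, float]:
    """(Fisher p, log carrier OR) for one gene's collapsed carrier table.

    Zero cells get the Haldane–Anscombe 0.5 continuity correction in the
    effect estimate only; the exact p-value needs no correction.
    """
    if case_n == 0 or control_n == 0:
        raise ValueError("both cohort arms must be non-empty")
    a, b = case_carriers, case_n - case_carriers
    c, d = control_carriers, control_n - control_carriers
    if a + c == 0 or b + d == 0:
        p = 1.0
    else:
        p = fisher_two_tailed(ContingencyTable(a, b, c, d, "carrier"))
    if min(a, b, c, d) == 0:
        a_, b_, c_, d_ = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        a_, b_, c_, d_ = a, b, c, d
    effect = math.log((a_ * d_) / (b_ * c_))
    return p, effect


def run_burden_scan(
    genotypes: CarrierMatrix,
    qualifying: Mapping[str, Sequence[VariantKey]],
    adjust: bool = True,
) -> list[GeneBurdenResult]:
    """Collapse and test every gene with qualifying variants; BH across genes."""
    indicators = collapse_to_carriers(genotypes, qualifying)
    case_mask = genotypes.case_mask
    case_n = int(case_mask.sum())
    control_n = genotypes.n_samples - case_n
    genes = sorted(indicators)
    raw: list[tuple[str, int, int, float, float]] = []
    for gene in genes:
        carrier = indicators[gene]
        cc = int((carrier & case_mask).sum())
        ctc = int((carrier & ~case_mask).sum())
        p, effect = burden_test(gene, cc, case_n, ctc, control_n)
        raw.append((gene, cc, ctc, p, effect))
    p_adj = bh_adjust([r[3] for r in raw]) if adjust else [r[3] for r in raw]
    return [
        GeneBurdenResult(
            gene=g,
            case_carriers=cc,
            case_n=case_n,
            control_carriers=ctc,
            control_n=control_n,
            p_raw=p,
            p_fdr=pf,
            effect=eff,
        )
        for (g, cc, ctc, p, eff), pf in zip(raw, p_adj)
    ]


@dataclass(frozen=True)
class CutoffDiagnostic:
    cutoff: float
    n_variants_removed: int
    r_squared: Optional[float]  # None when the burden scan was degenerate


def select_depth_cutoff(
    candidate_cutoffs: Sequence[float],
    variants: Sequence[AnnotatedVariant],
    depths: Sequence[DepthRecord],
    genotypes: CarrierMatrix,
    filtered_cohort: str,
    qualifying_genes: Optional[Mapping[str, Sequence[VariantKey]]] = None,
    tolerance: float = 0.01,
) -> tuple[float, list[CutoffDiagnostic]]:
    """Choose the mean-depth cutoff balancing calibration against data loss.

    For each candidate cutoff the gene-wide burden scan is re-run on the
    depth-filtered variant set and its QQ R² recorded alongside the number of
    variants removed.  The chosen cutoff is the *smallest* candidate whose R²
    lies within ``tolerance`` of the maximum across candidates, so variants
    are only sacrificed when they demonstrably improve calibration.
    """
    if len(candidate_cutoffs) < 1:
        raise ValueError("at least one candidate cutoff is required")
    if len(candidate_cutoffs) == 1:
        return float(candidate_cutoffs[0]), [
            CutoffDiagnostic(float(candidate_cutoffs[0]), 0, None)
        ]
    diagnostics: list[CutoffDiagnostic] = []
    for cutoff in candidate_cutoffs:
        retained = depth_filter(variants, depths, {filtered_cohort: cutoff})
        retained_keys = {v.key for v in retained}
        qualifying: dict[str, list[VariantKey]] = {}
        source = (
            qualifying_genes
            if qualifying_genes is not None
            else _group_by_gene(variants)
        )
        for gene, keys in source.items():
            kept = [k for k in keys if k in retained_keys]
            if kept:
                qualifying[gene] = kept
        try:
            results = run_burden_scan(genotypes, qualifying, adjust=False)
            r2 = qq_r_squared([r.p_raw for r in results])
        except ValueError:
            r2 = None
        diagnostics.append(
            CutoffDiagnostic(float(cutoff), len(variants) - len(retained), r2)
        )
    valid = [d for d in diagnostics if d.r_squared is not None]
    if not valid:
        raise ValueError("all candidate cutoffs gave degenerate burden scans")
    best_r2 = max(d.r_squared for d in valid)  # type: ignore[type-var]
    eligible = [d for d in valid if d.r_squared >= best_r2 - tolerance]
    chosen = min(eligible, key=lambda d: d.cutoff)
    return chosen.cutoff, diagnostics


def _group_by_gene(
    variants: Sequence[AnnotatedVariant],
) -> dict[str, list[VariantKey]]:
    grouped: dict[str, list[VariantKey]] = {}
    for v in variants:
        grouped.setdefault(v.gene, []).append(v.key)
    return grouped
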
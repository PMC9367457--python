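"""Exact 2×2 case-control inference and dual-cohort shortlisting.

Variant-level association compares the alternate-allele frequency of each
candidate variant in the case cohort against (a) the local control cohort and
(b) an external reference panel, using the two-tailed Fisher exact test and
the conditional maximum-likelihood odds ratio with exact confidence limits.
Variants absent from the panel are assumed to have zero allele count with a
linearly interpolated allele number when they lie within 300 nt of a valid
panel site.  p-values are adjusted per comparison with Benjamini–Hochberg, and
a variant is shortlisted when it is significantly *more* common in cases in
both comparisons at FDR q.

Two-sided rule
--------------
``fisher_two_tailed`` uses the point-probability rule: the p-value is the sum
of hypergeometric point probabilities, over all tables with the observed
margins, that do not exceed the probability of the observed table.  Ties are
compared with a 1e-12 relative tolerance, which is far below the smallest
possible relative gap between two distinct hypergeometric point masses at the
table sizes this pipeline tests, so the rule is effectively exact.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import hypergeom
from scipy.stats.contingency import odds_ratio as _scipy_odds_ratio
from statsmodels.stats.multitest import multipletests

from .cohort_io import AnnotatedVariant, CohortAlleleCounts, VariantKey

__all__ = [
    "ContingencyTable",
    "AssociationResult",
    "fisher_two_tailed",
    "odds_ratio_exact",
    "interpolate_allele_number",
    "bh_adjust",
    "dual_cohort_shortlist",
    "associate_cohort",
]

#: nt window within which a panel-absent variant borrows a neighbour's AN
PANEL_INTERPOLATION_WINDOW = 300


@dataclass(frozen=True)
class ContingencyTable:
    """A 2×2 count table: (exposed, unexposed) × (case, control).

    ``a``/``b`` are exposed/unexposed cases, ``c``/``d`` exposed/unexposed
    controls.  ``level`` records whether counts are alleles or carriers.
    """

    a: int
    b: int
    c: int
    d: int
    level: str = "allele"

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.level not in {"allele", "carrier"}:
            raise ValueError(f"unknown level {self.level!r}")

    @property
    def case_n(self) -> int:
        return self.a + self.b

    @property
    def control_n(self) -> int:
        return self.c + self.d

    @property
    def case_freq(self) -> float:
        return self.a / self.case_n

    @property
    def control_freq(self) -> float:
        return self.c / self.control_n

    def transpose_groups(self) -> "ContingencyTable":
        return ContingencyTable(self.c, self.d, self.a, self.b, self.level)


@dataclass(frozen=True)
class AssociationResult:
    variant_key: VariantKey
    table: ContingencyTable
    or_estimate: float  # may be 0.0 or math.inf
    ci_low: float
    ci_high: float
    p_raw: float
    p_fdr: float
    comparison_label: str


def _check_margins(t: ContingencyTable) -> None:
    if t.case_n == 0 or t.control_n == 0 or (t.a + t.c) == 0 or (t.b + t.d) == 0:
        raise ValueError(f"degenerate margins in table {t}: exact test undefined")


def fisher_two_tailed(table: ContingencyTable) -> float:
    """Two-tailed Fisher exact p-value under the point-probability rule."""
    _check_margins(table)
    n_total = table.a + table.b + table.c + table.d
    n_case = table.case_n
    k_exposed = table.a + table.c
    lo = max(0, k_exposed - table.control_n)
    hi = min(n_case, k_exposed)
    xs = np.arange(lo, hi + 1)
    logp = hypergeom.logpmf(xs, n_total, k_exposed, n_case)
    obs = logp[table.a - lo]
    # include all tables whose point probability <= observed, with a relative
    # tie tolerance far below the minimum gap between distinct point masses
    include = logp <= obs + 1e-12
    if include.all():
        return 1.0
    p = float(np.exp(logp[include]).sum())
    return min(p, 1.0)


# -- conditional MLE odds ratio ---------------------------------------------


def odds_ratio_exact(
    table: ContingencyTable, conf_level: float = 0.95
) -> tuple[float, float, float]:
    """Conditional-MLE odds ratio with exact confidence limits.

    The point estimate maximises Fisher's noncentral hypergeometric
    likelihood of the table given its margins; the confidence interval inverts
    the exact conditional test with ``(1 - conf_level) / 2`` in each tail.
    Degenerate exposed cells give one-sided results: estimate ``inf`` when no
    control is exposed (but some case is), ``0.0`` when no case is exposed
    (but some control is).
    """
    if table.a == 0 and table.c == 0:
        raise ValueError("no exposed individuals in either group: odds ratio undefined")
    _check_margins(table)
    res = _scipy_odds_ratio(
        [[table.a, table.b], [table.c, table.d]], kind="conditional"
    )
    ci = res.confidence_interval(confidence_level=conf_level)
    return float(res.statistic), float(ci.low), float(ci.high)


# -- reference-panel allele-number interpolation ----------------------------


def interpolate_allele_number(
    pos: int, panel_sites: Sequence[tuple[int, int]]
) -> Optional[int]:
    """Allele number to assume for a variant absent from the reference panel.

    ``panel_sites`` are ``(pos, an)`` pairs for valid panel sites on the same
    chromosome, sorted by position.  If sites flank ``pos`` on both sides and
    the nearer one is within 300 nt, the two flanking ANs are linearly
    interpolated at ``pos`` (rounded to the nearest even integer so the result
    remains a valid diploid allele number).  With a site within 300 nt on one
    side only, that site's AN is used.  With no site within 300 nt the variant
    is not testable against the panel and ``None`` is returned.
    """
    if not panel_sites:
        return None
    positions = [p for p, _ in panel_sites]
    if any(b < a for a, b in zip(positions, positions[1:])):
        raise ValueError("panel_sites must be sorted by position")
    left = [(p, an) for p, an in panel_sites if p <= pos]
    right = [(p, an) for p, an in panel_sites if p >= pos]
    left_site = left[-1] if left else None
    right_site = right[0] if right else None
    if left_site and left_site[0] == pos:
        return left_site[1]
    d_left = pos - left_site[0] if left_site else math.inf
    d_right = right_site[0] - pos if right_site else math.inf
    if min(d_left, d_right) > PANEL_INTERPOLATION_WINDOW:
        return None
    if left_site and right_site:
        (p0, an0), (p1, an1) = left_site, right_site
        an = an0 + (an1 - an0) * (pos - p0) / (p1 - p0)
    elif left_site and d_left <= PANEL_INTERPOLATION_WINDOW:
        an = left_site[1]
    else:
        an = right_site[1]  # type: ignore[index]
    return int(2 * round(an / 2.0))


# -- multiple testing --------------------------------------------------------


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


# -- cohort-level association ------------------------------------------------


def associate_cohort(
    variants: Sequence[AnnotatedVariant],
    case_counts: dict[VariantKey, CohortAlleleCounts],
    control_counts: dict[VariantKey, CohortAlleleCounts],
    comparison_label: str,
    conf_level: float = 0.95,
    compute_ci: bool = True,
    adjust: bool = True,
) -> list[AssociationResult]:
    """Allele-level exact association of each variant, with BH across the set.

    Variants without a control-count entry (untestable: panel-absent with no
    interpolable allele number) are excluded from the BH family with a
    warning.  ``adjust=False`` reports raw p-values in ``p_fdr`` unchanged —
    used when re-testing a previously shortlisted set in a validation cohort,
    which forms no new testing family.
    """
    keys_tables: list[tuple[VariantKey, ContingencyTable]] = []
    for v in variants:
        key = v.key
        if key not in case_counts:
            raise KeyError(f"no case allele counts for {key}")
        if key not in control_counts:
            warnings.warn(f"variant {key} untestable in {comparison_label}: skipped")
            continue
        ca, co = case_counts[key], control_counts[key]
        table = ContingencyTable(ca.ac, ca.an - ca.ac, co.ac, co.an - co.ac, "allele")
        keys_tables.append((key, table))
    results: list[AssociationResult] = []
    # a variant observed in neither group carries no evidence: p = 1
    p_raw = [
        1.0 if (t.a == 0 and t.c == 0) else fisher_two_tailed(t) for _, t in keys_tables
    ]
    p_adj = bh_adjust(p_raw) if adjust else list(p_raw)
    for (key, t), pr, pf in zip(keys_tables, p_raw, p_adj):
        if t.a == 0 and t.c == 0:
            est, lo, hi = float("nan"), float("nan"), float("nan")
        elif compute_ci:
            est, lo, hi = odds_ratio_exact(t, conf_level)
        else:
            est = _scipy_odds_ratio([[t.a, t.b], [t.c, t.d]], kind="conditional").statistic
            lo, hi = float("nan"), float("nan")
        results.append(
            AssociationResult(
                variant_key=key,
                table=t,
                or_estimate=float(est),
                ci_low=lo,
                ci_high=hi,
                p_raw=pr,
                p_fdr=pf,
                comparison_label=comparison_label,
            )
        )
    return results


def dual_cohort_shortlist(
    results_local: Sequence[AssociationResult],
    results_panel: Sequence[AssociationResult],
    q: float = 0.10,
) -> list[VariantKey]:
    """Variants significantly more common in cases in *both* comparisons.

    Requires FDR-adjusted p < ``q`` and case frequency above control frequency
    in both the local-control and reference-panel comparisons.  Keys present
    in only one result list are excluded with a warning.
    """
    local = {r.variant_key: r for r in results_local}
    panel = {r.variant_key: r for r in results_panel}
    only = set(local) ^ set(panel)
    for key in sorted(only):
        warnings.warn(f"variant {key} present in only one comparison: excluded")
    shortlisted = []
    for key in [k for k in local if k in panel]:
        rl, rp = local[key], panel[key]
        if (
            rl.p_fdr < q
            and rp.p_fdr < q
            and rl.table.case_freq > rl.table.control_freq
            and rp.table.case_freq > rp.table.control_freq
        ):
            shortlisted.append(key)
    return shortlisted
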
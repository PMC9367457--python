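"""Replicated calibration and power experiments on synthetic cohorts.

These drive the pipeline end to end over many simulated studies to measure
its operating characteristics under known truth: the false-discovery
proportion of the dual-cohort shortlist on null cohorts, and the recovery
power for planted risk variants at realistic effect sizes.  They are the
package's own evidence that the wiring — generator, cascade, exact tests,
FDR, shortlist rule — behaves as designed; they make no claim about any
particular real dataset.
"""

from __future__ import annotations

import numpy as np

from .association import associate_cohort, dual_cohort_shortlist
from .cohort_io import CohortAlleleCounts, VariantKey
from .pipeline import _allele_counts_from_matrix, _panel_counts_for
from .prioritization import CascadeConfig, run_cascade
from .synthetic import (
    PlantedEffect,
    SimulatedCohort,
    SimulationConfig,
    simulate_cancer_gene_sources,
    simulate_cohort,
)

__all__ = [
    "dual_shortlist_for_cohort",
    "null_false_discovery_proportion",
    "planted_recovery_power",
]


def dual_shortlist_for_cohort(
    sim: SimulatedCohort,
    variants=None,
    q: float = 0.10,
) -> list[VariantKey]:
    """Dual-cohort shortlist (local-control and panel comparisons) for a
    simulated study, on ``variants`` (defaults to all simulated variants)."""
    import warnings

    if variants is None:
        variants = sim.variants
    keys = [v.key for v in variants]
    case_counts = _allele_counts_from_matrix(sim.genotypes, keys, "case", "discovery")
    local_counts = _allele_counts_from_matrix(sim.genotypes, keys, "control", "local")
    panel_counts = _panel_counts_for(variants, sim.panel_counts)
    with warnings.catch_warnings():
        # panel-untestable variants are an expected, tallied outcome here
        warnings.simplefilter("ignore", UserWarning)
        results_local = associate_cohort(
            variants, case_counts, local_counts, "local", compute_ci=False
        )
        results_panel = associate_cohort(
            variants, case_counts, panel_counts, "panel", compute_ci=False
        )
        return dual_cohort_shortlist(results_local, results_panel, q=q)


def null_false_discovery_proportion(
    n_cohorts: int = 50,
    seed: int = 0,
    n_cases: int = 200,
    n_controls: int = 2000,
    n_variants: int = 500,
    q: float = 0.10,
) -> float:
    """Mean false-discovery proportion of the shortlist over null cohorts.

    Every shortlisted variant on a cohort with no planted effects is a false
    discovery, so each cohort contributes V / max(R, 1) with V = R.
    """
    fdps = []
    for rep in range(n_cohorts):
        config = SimulationConfig(
            n_cases=n_cases,
            n_controls=n_controls,
            n_validation_cases=1,
            n_validation_controls=1,
            n_panel=9626,
            n_variants=n_variants,
            n_genes=max(1, n_variants // 5),
            seed=seed + rep,
        )
        sim = simulate_cohort(config)
        shortlisted = dual_shortlist_for_cohort(sim, q=q)
        fdps.append(1.0 if shortlisted else 0.0)
    return float(np.mean(fdps))


def planted_recovery_power(
    n_replicates: int = 100,
    seed: int = 0,
    carrier_or: float = 10.0,
    maf: float = 0.005,
    n_cases: int = 119,
    n_controls: int = 1337,
    n_variants: int = 200,
    q: float = 0.10,
) -> float:
    """Fraction of replicates whose planted variant survives the full
    variant-discovery path: prioritization cascade, then dual-cohort exact
    association and FDR shortlisting at the study's cohort sizes."""
    hits = 0
    for rep in range(n_replicates):
        config = SimulationConfig(
            n_cases=n_cases,
            n_controls=n_controls,
            n_validation_cases=1,
            n_validation_controls=1,
            n_panel=9626,
            n_variants=n_variants,
            n_genes=max(1, n_variants // 5),
            planted_effects=[PlantedEffect("GENE0001", carrier_or, maf=maf)],
            seed=seed + rep,
        )
        sim = simulate_cohort(config)
        sources = simulate_cancer_gene_sources(
            sorted({v.gene for v in sim.variants}), ["GENE0001"], seed=seed + rep
        )
        cascade = CascadeConfig(cancer_gene_sources=sources)
        selected, _ = run_cascade(sim.variants, sim.genotypes, cascade)
        shortlisted = set(dual_shortlist_for_cohort(sim, selected, q=q))
        planted = {k for k, f in sim.truth.planted.items() if f}
        if planted <= shortlisted:
            hits += 1
    return hits / n_replicates
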
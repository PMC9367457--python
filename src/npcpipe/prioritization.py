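"""Variant prioritization cascade.

Selects "rare pathogenic variants in known cancer genes" in four stages:

1. recurrence — carried by at least ``min_case_carriers`` affected patients
   (singletons are retained separately: they are excluded from variant-level
   tests but still enter gene-level burden tests);
2. rarity — alternate-allele frequency below ``maf_threshold`` in *both* the
   local control cohort and the external reference panel, where a missing
   frequency record counts as rare (absence from a panel cannot disqualify);
3. predicted pathogenicity — nonsynonymous SNV with CADD phred strictly above
   ``cadd_threshold``, or any loss-of-function class regardless of score;
4. known cancer gene — gene present in at least ``min_source_count`` of the
   supplied cancer-gene source lists.

QC failures and manually excluded (alignment-review) variants are dropped
before stage 1.  The three per-variant predicates commute; recurrence must
run first because it consumes the genotype matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .cohort_io import (
    LOF_CLASSES,
    AnnotatedVariant,
    CarrierMatrix,
    FuncClass,
    GeneSet,
    VariantKey,
)

__all__ = [
    "CascadeConfig",
    "CascadeReport",
    "stage_recurrence",
    "stage_rare",
    "stage_pathogenic",
    "stage_cancer_gene",
    "variant_qualifies",
    "run_cascade",
]


@dataclass
class CascadeConfig:
    """Thresholds of the prioritization cascade.

    Defaults: recurrence in >= 2 affected patients; MAF < 1% in both control
    panels; CADD phred > 20 (strictly) for nonsynonymous SNVs with
    loss-of-function classes always retained; gene in >= 2 of the cancer-gene
    sources (five slots by convention).
    """

    min_case_carriers: int = 2
    maf_threshold: float = 0.01
    cadd_threshold: float = 20.0
    lof_classes: frozenset[FuncClass] = LOF_CLASSES
    min_source_count: int = 2
    cancer_gene_sources: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.min_case_carriers < 1:
            raise ValueError("min_case_carriers must be >= 1")
        if not (0 < self.maf_threshold <= 1):
            raise ValueError("maf_threshold must lie in (0, 1]")
        if self.cadd_threshold < 0:
            raise ValueError("cadd_threshold must be >= 0")
        if self.cancer_gene_sources and self.min_source_count > len(
            self.cancer_gene_sources
        ):
            raise ValueError("min_source_count exceeds the number of sources")


@dataclass
class CascadeReport:
    """Per-stage accounting: how many variants survived each filter."""

    total_input: int = 0
    total_pass_qc: int = 0
    recurrent: int = 0
    rare: int = 0
    pathogenic: int = 0
    in_cancer_genes: int = 0
    n_singletons: int = 0
    #: variant key -> name of the stage that eliminated it ("selected" if none)
    stage_of_elimination: dict[VariantKey, str] = field(default_factory=dict)

    def counts(self) -> list[int]:
        return [
            self.total_pass_qc,
            self.recurrent,
            self.rare,
            self.pathogenic,
            self.in_cancer_genes,
        ]


def stage_recurrence(
    variants: Sequence[AnnotatedVariant],
    genotypes: CarrierMatrix,
    min_case_carriers: int = 2,
) -> tuple[list[AnnotatedVariant], list[AnnotatedVariant]]:
    """Split variants into (recurrent, singleton) by affected-carrier count.

    Recurrent variants have >= ``min_case_carriers`` case carriers; variants
    carried by at least one but fewer cases are singletons (kept for the
    gene-based tests).  Variants carried by no case fall in neither list.
    """
    recurrent: list[AnnotatedVariant] = []
    singletons: list[AnnotatedVariant] = []
    for v in variants:
        n = genotypes.case_carrier_count(v.key)  # raises KeyError if absent
        if n >= min_case_carriers:
            recurrent.append(v)
        elif n >= 1:
            singletons.append(v)
    return recurrent, singletons


def stage_rare(variant: AnnotatedVariant, maf_threshold: float = 0.01) -> bool:
    """True iff the variant is rare in both control panels.

    A missing frequency means the variant has no record in that panel; such
    variants pass (variants at frequency zero in all controls must survive).
    """
    local_ok = variant.maf_local is None or variant.maf_local < maf_threshold
    panel_ok = variant.gnomad_af is None or variant.gnomad_af < maf_threshold
    return local_ok and panel_ok


def stage_pathogenic(
    variant: AnnotatedVariant,
    cadd_threshold: float = 20.0,
    lof_classes: frozenset[FuncClass] = LOF_CLASSES,
) -> bool:
    """True iff predicted pathogenic: high-CADD nonsynonymous SNV or LoF.

    The CADD comparison is strict (a score of exactly the threshold fails);
    loss-of-function classes pass regardless of score.
    """
    if variant.func_class in lof_classes:
        return True
    return (
        variant.func_class is FuncClass.NONSYNONYMOUS_SNV
        and variant.cadd_phred > cadd_threshold
    )


def stage_cancer_gene(
    gene: str, sources: Sequence[GeneSet], min_source_count: int = 2
) -> bool:
    """True iff ``gene`` appears in at least ``min_source_count`` sources."""
    if not sources:
        raise ValueError("at least one cancer-gene source is required")
    return sum(1 for s in sources if gene in s) >= min_source_count


def variant_qualifies(variant: AnnotatedVariant, config: CascadeConfig) -> bool:
    """Per-variant predicate for gene-level burden qualification.

    Identical to the cascade minus the recurrence stage: gene-based tests
    count carriers of *any* rare pathogenic variant in the gene, including
    singletons and variants carried only by controls.
    """
    if not variant.qc_pass or variant.igv_excluded:
        return False
    if not stage_rare(variant, config.maf_threshold):
        return False
    if not stage_pathogenic(variant, config.cadd_threshold, config.lof_classes):
        return False
    if config.cancer_gene_sources:
        return stage_cancer_gene(
            variant.gene, config.cancer_gene_sources, config.min_source_count
        )
    return True


def run_cascade(
    variants: Sequence[AnnotatedVariant],
    genotypes: Optional[CarrierMatrix],
    config: CascadeConfig,
) -> tuple[list[AnnotatedVariant], CascadeReport]:
    """Apply the full cascade in order and account for every variant.

    ``genotypes`` may be ``None`` only when ``variants`` is empty.  The
    returned report's stage counts are monotone non-increasing; running the
    cascade on its own output returns the same set (idempotence).
    """
    report = CascadeReport(total_input=len(variants))
    if not variants:
        return [], report
    if genotypes is None:
        raise ValueError("genotypes are required when variants are present")

    qc_passing = []
    for v in variants:
        if v.qc_pass and not v.igv_excluded:
            qc_passing.append(v)
        else:
            report.stage_of_elimination[v.key] = "qc"
    report.total_pass_qc = len(qc_passing)

    recurrent, singletons = stage_recurrence(
        qc_passing, genotypes, config.min_case_carriers
    )
    report.n_singletons = len(singletons)
    surviving = set(v.key for v in recurrent)
    for v in qc_passing:
        if v.key not in surviving:
            report.stage_of_elimination[v.key] = "recurrence"
    report.recurrent = len(recurrent)

    rare = [v for v in recurrent if stage_rare(v, config.maf_threshold)]
    for v in recurrent:
        if not stage_rare(v, config.maf_threshold):
            report.stage_of_elimination[v.key] = "rare"
    report.rare = len(rare)

    pathogenic = [
        v for v in rare if stage_pathogenic(v, config.cadd_threshold, config.lof_classes)
    ]
    for v in rare:
        if not stage_pathogenic(v, config.cadd_threshold, config.lof_classes):
            report.stage_of_elimination[v.key] = "pathogenic"
    report.pathogenic = len(pathogenic)

    if config.cancer_gene_sources:
        selected = [
            v
            for v in pathogenic
            if stage_cancer_gene(
                v.gene, config.cancer_gene_sources, config.min_source_count
            )
        ]
        for v in pathogenic:
            if v.key not in {s.key for s in selected}:
                report.stage_of_elimination[v.key] = "cancer_gene"
    else:
        selected = list(pathogenic)
    report.in_cancer_genes = len(selected)
    for v in selected:
        report.stage_of_elimination[v.key] = "selected"
    return selected, report
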
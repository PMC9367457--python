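"""Synthetic case-control cohorts with the structure the analysis assumes.

The generator's defaults emulate the study conditions the pipeline was built
for: a discovery cohort of 119 cases against 1337 local controls, a
validation cohort of 156 cases against 9770 controls, a large external
reference panel (9626 individuals) with per-site allele-number jitter, rare
control-population allele frequencies (log-uniform over [1e-4, 5e-2]),
planted risk variants parameterized by their *carrier* odds ratio, cohort-
specific sequencing depth, and families with Mendelian transmission.

Model
-----
* Control genotypes at a variant with control-population MAF ``m`` are drawn
  Binomial(2, m) per individual (Hardy–Weinberg, no linkage disequilibrium).
* Case genotypes tilt the carrier probability so the carrier odds ratio
  equals the planted value: with control carrier probability
  ``q0 = 1 - (1 - m)^2``, case carriers occur with probability
  ``q1 = OR·q0 / (1 - q0 + OR·q0)``; carriers are homozygous with the same
  conditional probability ``m / (2 - m)`` as controls.
* Reference-panel allele counts are Binomial(AN, m) with AN jittered ±10%
  around 2·n_panel (rounded to even); a configurable fraction of variants is
  withheld from the panel entirely, to exercise the allele-number
  interpolation rule.
* CADD scores come from a two-component model: predicted-deleterious
  variants ~ Normal(25, 3) truncated at 0, benign ~ Normal(8, 4) truncated
  at 0, so a >20 threshold is informative but imperfect.  Planted variants
  are deleterious nonsynonymous SNVs.
* Per-variant mean depth per cohort ~ Normal(cohort mean, cohort sd),
  truncated at 0.

Not modelled: linkage disequilibrium, population structure, relatedness
beyond explicit pedigrees, sequencing error, genotype missingness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .cohort_io import (
    AnnotatedVariant,
    CarrierMatrix,
    CohortAlleleCounts,
    DepthRecord,
    FuncClass,
    GeneSet,
    Pedigree,
    PedigreeMember,
    VariantKey,
)

__all__ = [
    "PlantedEffect",
    "SimulationConfig",
    "SyntheticTruth",
    "SimulatedCohort",
    "simulate_cohort",
    "simulate_cancer_gene_sources",
    "simulate_family",
    "write_simulation",
]


@dataclass(frozen=True)
class PlantedEffect:
    gene: str
    carrier_odds_ratio: float
    n_variants: int = 1
    maf: Optional[float] = None  # control-population MAF; None -> drawn

    def __post_init__(self) -> None:
        if self.carrier_odds_ratio <= 0:
            raise ValueError("carrier odds ratio must be > 0")
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")


@dataclass
class SimulationConfig:
    """Cohort sizes, variant spectrum and effect structure of one simulation."""

    n_cases: int = 119
    n_controls: int = 1337
    n_validation_cases: int = 156
    n_validation_controls: int = 9770
    n_panel: int = 9626
    n_variants: int = 200
    n_genes: int = 40
    maf_range: tuple[float, float] = (1e-4, 5e-2)
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    prop_lof: float = 0.10
    prop_deleterious: float = 0.30
    prop_synonymous: float = 0.10
    cadd_deleterious: tuple[float, float] = (25.0, 3.0)
    cadd_benign: tuple[float, float] = (8.0, 4.0)
    depth_model: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"discovery": (80.0, 15.0), "control": (55.0, 12.0)}
    )
    panel_withheld_frac: float = 0.05
    panel_an_jitter: float = 0.10
    prop_cancer_gene: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_cases",
            "n_controls",
            "n_validation_cases",
            "n_validation_controls",
            "n_panel",
            "n_variants",
            "n_genes",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("prop_lof", "prop_deleterious", "prop_synonymous",
                     "panel_withheld_frac", "prop_cancer_gene"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if not (0 < self.maf_range[0] <= self.maf_range[1] < 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi < 0.5")
        n_planted = sum(e.n_variants for e in self.planted_effects)
        if n_planted > self.n_variants:
            raise ValueError("more planted variants than n_variants")


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated cohort, for recovery tests."""

    true_maf: dict[VariantKey, float]
    true_carrier_or: dict[VariantKey, float]
    planted: dict[VariantKey, bool]


@dataclass
class SimulatedCohort:
    variants: list[AnnotatedVariant]
    genotypes: CarrierMatrix  # discovery cases + local controls
    validation_genotypes: CarrierMatrix
    panel_counts: dict[VariantKey, CohortAlleleCounts]
    depths: list[DepthRecord]
    truth: SyntheticTruth


_BASES = np.array(list("ACGT"))


def _draw_genotypes(
    rng: np.random.Generator, n: int, maf: float, carrier_or: float
) -> np.ndarray:
    """Dosages for ``n`` individuals at one variant with a carrier-odds tilt."""
    q0 = 1.0 - (1.0 - maf) ** 2
    if carrier_or == 1.0:
        return rng.binomial(2, maf, size=n).astype(np.int8)
    odds = carrier_or * q0 / (1.0 - q0)
    q1 = odds / (1.0 + odds)
    carrier = rng.random(n) < q1
    hom = rng.random(n) < (maf / (2.0 - maf))
    return np.where(carrier, np.where(hom, 2, 1), 0).astype(np.int8)


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate one full synthetic study (deterministic under the seed)."""
    rng = np.random.default_rng(config.seed)
    gene_names = [f"GENE{i:04d}" for i in range(1, config.n_genes + 1)]

    # -- variant scaffold: positions, alleles, gene assignment ---------------
    spacing = rng.integers(60, 420, size=config.n_variants)
    positions = 10_000 + np.cumsum(spacing)
    refs = rng.choice(_BASES, size=config.n_variants)
    alts = np.array(
        [rng.choice([b for b in _BASES if b != r]) for r in refs]
    )
    genes = [gene_names[i % config.n_genes] for i in range(config.n_variants)]

    # planted variants occupy the first slots of their gene's indices
    planted_or = np.ones(config.n_variants)
    planted_flag = np.zeros(config.n_variants, dtype=bool)
    planted_maf: dict[int, float] = {}
    cursor = 0
    for eff in config.planted_effects:
        for _ in range(eff.n_variants):
            genes[cursor] = eff.gene
            planted_or[cursor] = eff.carrier_odds_ratio
            planted_flag[cursor] = True
            if eff.maf is not None:
                planted_maf[cursor] = eff.maf
            cursor += 1

    lo, hi = config.maf_range
    mafs = np.exp(rng.uniform(np.log(lo), np.log(hi), size=config.n_variants))
    for idx, m in planted_maf.items():
        mafs[idx] = m

    # functional classes and CADD scores
    func_classes: list[FuncClass] = []
    deleterious = np.zeros(config.n_variants, dtype=bool)
    u = rng.random(config.n_variants)
    for j in range(config.n_variants):
        if planted_flag[j]:
            func_classes.append(FuncClass.NONSYNONYMOUS_SNV)
            deleterious[j] = True
        elif u[j] < config.prop_lof:
            func_classes.append(FuncClass.FRAMESHIFT_INDEL)
            deleterious[j] = True
        elif u[j] < config.prop_lof + config.prop_synonymous:
            func_classes.append(FuncClass.SYNONYMOUS)
        else:
            func_classes.append(FuncClass.NONSYNONYMOUS_SNV)
            deleterious[j] = rng.random() < config.prop_deleterious
    mu_d, sd_d = config.cadd_deleterious
    mu_b, sd_b = config.cadd_benign
    cadd = np.where(
        deleterious,
        rng.normal(mu_d, sd_d, size=config.n_variants),
        rng.normal(mu_b, sd_b, size=config.n_variants),
    ).clip(min=0.0)

    # -- genotypes -----------------------------------------------------------
    def build_matrix(n_cases: int, n_controls: int, prefix: str) -> CarrierMatrix:
        sample_ids = [f"case_{prefix}{i:05d}" for i in range(n_cases)] + [
            f"ctrl_{prefix}{i:05d}" for i in range(n_controls)
        ]
        phen = ["case"] * n_cases + ["control"] * n_controls
        dosage = np.zeros((n_cases + n_controls, config.n_variants), dtype=np.int8)
        for j in range(config.n_variants):
            dosage[:n_cases, j] = _draw_genotypes(rng, n_cases, mafs[j], planted_or[j])
            dosage[n_cases:, j] = _draw_genotypes(rng, n_controls, mafs[j], 1.0)
        keys = [
            (str("1"), int(positions[j]), str(refs[j]), str(alts[j]))
            for j in range(config.n_variants)
        ]
        return CarrierMatrix(
            sample_ids=sample_ids, variant_keys=keys, dosage=dosage, phenotype=phen
        )

    discovery = build_matrix(config.n_cases, config.n_controls, "")
    validation = build_matrix(
        config.n_validation_cases, config.n_validation_controls, "v"
    )
    keys = discovery.variant_keys

    # -- reference panel -----------------------------------------------------
    withheld = rng.random(config.n_variants) < config.panel_withheld_frac
    panel_counts: dict[VariantKey, CohortAlleleCounts] = {}
    panel_an = np.zeros(config.n_variants, dtype=int)
    panel_ac = np.zeros(config.n_variants, dtype=int)
    for j in range(config.n_variants):
        jitter = rng.uniform(1 - config.panel_an_jitter, 1 + config.panel_an_jitter)
        an = int(2 * round(config.n_panel * jitter))
        ac = int(rng.binomial(an, mafs[j]))
        panel_an[j], panel_ac[j] = an, ac
        if not withheld[j]:
            panel_counts[keys[j]] = CohortAlleleCounts(ac=ac, an=an, cohort_label="panel")

    # -- annotated variant table --------------------------------------------
    variants: list[AnnotatedVariant] = []
    for j in range(config.n_variants):
        ctrl_ac, ctrl_an = discovery.allele_counts(keys[j], "control")
        variants.append(
            AnnotatedVariant(
                chrom=keys[j][0],
                pos=keys[j][1],
                ref=keys[j][2],
                alt=keys[j][3],
                gene=genes[j],
                func_class=func_classes[j],
                cadd_phred=float(cadd[j]),
                maf_local=ctrl_ac / ctrl_an,
                gnomad_af=None if withheld[j] else panel_ac[j] / panel_an[j],
                gnomad_an=None if withheld[j] else int(panel_an[j]),
            )
        )

    # -- depths --------------------------------------------------------------
    depths: list[DepthRecord] = []
    for cohort, (mu, sd) in config.depth_model.items():
        vals = rng.normal(mu, sd, size=config.n_variants).clip(min=0.0)
        depths.extend(
            DepthRecord(variant_key=keys[j], cohort_label=cohort, mean_depth=float(vals[j]))
            for j in range(config.n_variants)
        )

    truth = SyntheticTruth(
        true_maf={keys[j]: float(mafs[j]) for j in range(config.n_variants)},
        true_carrier_or={keys[j]: float(planted_or[j]) for j in range(config.n_variants)},
        planted={keys[j]: bool(planted_flag[j]) for j in range(config.n_variants)},
    )
    return SimulatedCohort(
        variants=variants,
        genotypes=discovery,
        validation_genotypes=validation,
        panel_counts=panel_counts,
        depths=depths,
        truth=truth,
    )


def simulate_cancer_gene_sources(
    genes: Sequence[str],
    always_listed: Sequence[str],
    seed: int,
    n_sources: int = 5,
    prop_listed: float = 0.5,
) -> list[GeneSet]:
    """Five synthetic cancer-gene source lists.

    Genes in ``always_listed`` (e.g. planted risk genes) appear in at least
    two sources; every other gene is listed in >= 2 sources with probability
    ``prop_listed``, in exactly one source with a small probability, else in
    none — so the "at least two sources" filter is exercised in all regimes.
    """
    rng = np.random.default_rng(seed)
    membership: dict[int, set[str]] = {i: set() for i in range(n_sources)}
    always = set(always_listed)
    for gene in genes:
        if gene in always:
            k = int(rng.integers(2, n_sources + 1))
        else:
            u = rng.random()
            if u < prop_listed:
                k = int(rng.integers(2, n_sources + 1))
            elif u < prop_listed + 0.2:
                k = 1
            else:
                k = 0
        for src in rng.choice(n_sources, size=k, replace=False):
            membership[int(src)].add(gene)
    sets = []
    for i in range(n_sources):
        if not membership[i]:  # a source list may never be empty
            membership[i].add(genes[0] if genes else "PLACEHOLDER")
        sets.append(
            GeneSet(
                name=f"source_{i + 1}",
                genes=frozenset(membership[i]),
                description="synthetic cancer-gene source list",
            )
        )
    return sets


def write_simulation(
    sim: SimulatedCohort,
    sources: Sequence[GeneSet],
    out_dir: str,
) -> dict[str, str]:
    """Write a simulated cohort in the formats the pipeline readers consume.

    Produces ``variants.tsv``, ``discovery.vcf``, ``validation.vcf``,
    ``panel.tsv``, ``depths.tsv``, ``sources.gmt`` and ``truth.json`` under
    ``out_dir`` and returns the path map.
    """
    import json
    import os

    from . import cohort_io as cio

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "variants": os.path.join(out_dir, "variants.tsv"),
        "discovery_vcf": os.path.join(out_dir, "discovery.vcf"),
        "validation_vcf": os.path.join(out_dir, "validation.vcf"),
        "panel": os.path.join(out_dir, "panel.tsv"),
        "depths": os.path.join(out_dir, "depths.tsv"),
        "sources": os.path.join(out_dir, "sources.gmt"),
        "truth": os.path.join(out_dir, "truth.json"),
    }
    cio.write_annotated_variants(sim.variants, paths["variants"])
    cio.write_genotypes_vcf(sim.genotypes, paths["discovery_vcf"])
    cio.write_genotypes_vcf(sim.validation_genotypes, paths["validation_vcf"])
    cio.write_panel_counts(sim.panel_counts, paths["panel"])
    cio.write_depth_table(sim.depths, paths["depths"])
    cio.write_gene_sets_gmt(sources, paths["sources"])
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "|".join(map(str, k)): {
                    "maf": sim.truth.true_maf[k],
                    "carrier_or": sim.truth.true_carrier_or[k],
                    "planted": sim.truth.planted[k],
                }
                for k in sim.truth.true_maf
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    return paths


def simulate_family(
    n_affected: int,
    n_unaffected: int,
    planted_variant: VariantKey,
    seed: int,
    cosegregate: Optional[bool] = True,
    family_id: str = "FAM1",
) -> tuple[Pedigree, dict[str, bool]]:
    """A nuclear family with a planted variant transmitted from a het parent.

    Two (ungenotyped) parents and ``n_affected + n_unaffected`` genotyped
    siblings.  Each sibling inherits the variant allele from the heterozygous
    parent with probability 1/2 (Mendelian segregation).  ``cosegregate``
    then optionally overrides the pattern: ``True`` forces all affected
    siblings to carry and all unaffected not to (the fully co-segregating
    layout); ``False`` guarantees at least one discordant member; ``None``
    leaves pure Mendelian transmission.
    """
    if n_affected + n_unaffected < 2:
        raise ValueError("a family needs at least two siblings")
    rng = np.random.default_rng(seed)
    father, mother = f"{family_id}_F", f"{family_id}_M"
    members = [
        PedigreeMember(father, None, None, "male", False),
        PedigreeMember(mother, None, None, "female", False),
    ]
    carriers: dict[str, bool] = {}
    sib_ids = []
    for i in range(n_affected + n_unaffected):
        sid = f"{family_id}_S{i + 1}"
        sib_ids.append(sid)
        members.append(
            PedigreeMember(sid, father, mother, "unknown", affected=i < n_affected)
        )
        carriers[sid] = bool(rng.random() < 0.5)  # transmission from het parent

    if cosegregate is True:
        for i, sid in enumerate(sib_ids):
            carriers[sid] = i < n_affected
    elif cosegregate is False:
        for i, sid in enumerate(sib_ids):
            carriers[sid] = i < n_affected
        flip = sib_ids[int(rng.integers(len(sib_ids)))]
        carriers[flip] = not carriers[flip]
    return Pedigree(family_id=family_id, members=members), carriers
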
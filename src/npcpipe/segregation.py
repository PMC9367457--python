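"""Family co-segregation of candidate variants.

For each (variant, family) pair, carrier status is compared with affection
status among genotyped members.  A variant *segregates* when every genotyped
affected member carries it and no genotyped unaffected member does;
*contradicts* when no affected member carries it or every unaffected member
does; anything in between is *partial*.  A family without at least one
genotyped affected and one genotyped unaffected member is *uninformative*.

Penetrance modelling, LOD scores and phasing are out of scope: classification
is a deterministic rule on carrier counts, mirroring how fully penetrant
dominant patterns are read off small families.

``family_burden`` runs the same carrier collapsing as the gene burden module
on the family cohort (probands plus relatives), with affected members as the
"case" arm, to verify variant-level candidates at the gene level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .burden import burden_test
from .cohort_io import CarrierMatrix, Pedigree, VariantKey

__all__ = ["SegregationCall", "segregation_check", "family_burden", "FamilyBurdenRow"]


@dataclass(frozen=True)
class SegregationCall:
    variant_key: VariantKey
    family_id: str
    affected_carriers: int
    affected_total: int
    unaffected_carriers: int
    unaffected_total: int
    classification: str  # segregates | partial | contradicts | uninformative


def classify_counts(
    affected_carriers: int,
    affected_total: int,
    unaffected_carriers: int,
    unaffected_total: int,
) -> str:
    """Deterministic classification rule on (carrier, total) counts."""
    if affected_total < 1 or unaffected_total < 1:
        return "uninformative"
    if affected_carriers == affected_total and unaffected_carriers == 0:
        return "segregates"
    if affected_carriers == 0 or unaffected_carriers == unaffected_total:
        return "contradicts"
    return "partial"


def segregation_check(
    variant_key: VariantKey,
    pedigree: Pedigree,
    carriers: Mapping[str, bool],
) -> SegregationCall:
    """Classify one variant in one family.

    ``carriers`` maps sample id -> carrier status; pedigree members without an
    entry are ungenotyped and excluded from the counts.
    """
    genotyped = [m for m in pedigree.members if m.sample_id in carriers]
    skipped = len(pedigree.members) - len(genotyped)
    if skipped:
        import logging

        logging.getLogger(__name__).warning(
            "family %s: %d ungenotyped members excluded from segregation counts",
            pedigree.family_id,
            skipped,
        )
    aff = [m for m in genotyped if m.affected]
    unaff = [m for m in genotyped if not m.affected]
    ac = sum(1 for m in aff if carriers[m.sample_id])
    uc = sum(1 for m in unaff if carriers[m.sample_id])
    return SegregationCall(
        variant_key=variant_key,
        family_id=pedigree.family_id,
        affected_carriers=ac,
        affected_total=len(aff),
        unaffected_carriers=uc,
        unaffected_total=len(unaff),
        classification=classify_counts(ac, len(aff), uc, len(unaff)),
    )


@dataclass(frozen=True)
class FamilyBurdenRow:
    gene: str
    affected_carriers: int
    affected_total: int
    unaffected_carriers: int
    unaffected_total: int
    p_raw: float
    effect: float


def family_burden(
    genotypes: CarrierMatrix,
    qualifying: Mapping[str, Sequence[VariantKey]],
) -> list[FamilyBurdenRow]:
    """Gene-level carrier counts and exact test in the family cohort.

    ``genotypes`` holds probands and relatives with phenotype "case" for
    affected and "control" for unaffected members; all genotyped affected
    individuals are treated symmetrically.  Genes with no qualifying variant
    carried by any member are omitted (there is nothing to test).
    """
    from .burden import collapse_to_carriers

    indicators = collapse_to_carriers(genotypes, qualifying)
    case_mask = genotypes.case_mask
    n_aff = int(case_mask.sum())
    n_unaff = genotypes.n_samples - n_aff
    rows: list[FamilyBurdenRow] = []
    for gene in sorted(indicators):
        carrier = indicators[gene]
        ac = int((carrier & case_mask).sum())
        uc = int((carrier & ~case_mask).sum())
        if ac == 0 and uc == 0:
            continue
        p, effect = burden_test(gene, ac, n_aff, uc, n_unaff)
        rows.append(
            FamilyBurdenRow(
                gene=gene,
                affected_carriers=ac,
                affected_total=n_aff,
                unaffected_carriers=uc,
                unaffected_total=n_unaff,
                p_raw=p,
                effect=effect,
            )
        )
    return rows
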
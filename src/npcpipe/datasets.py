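"""Reference fixtures: published contingency counts of the NPC analysis.

The raw sequence data behind the NPC predisposition analysis are not
deposited, but every count this pipeline's statistics consume was printed:
per-variant allele counts in the discovery comparison (119 cases, 2n = 238,
vs 1337 local controls, 2n = 2674) and the validation comparison (156 cases,
2n = 312, vs up to 9770 controls with per-site allele numbers), per-gene
carrier counts from the burden tests, per-pathway individual carrier counts,
and the five-sibling family in which the FANCE variant co-segregated with
disease.  This module ships those counts as in-memory fixtures so the exact
2×2 machinery can be exercised against known results without external data.

Genotype-level objects built here (the family cohort, the FANCE sibship) are
synthetic stand-ins: carrier assignments are constructed to reproduce the
published counts, not real genotypes.
"""

from __future__ import annotations

import numpy as np

from .association import ContingencyTable
from .cohort_io import CarrierMatrix, GeneSet, Pedigree, PedigreeMember, VariantKey

__all__ = [
    "DISCOVERY_ALLELE_TABLES",
    "VALIDATION_ALLELE_TABLES",
    "BURDEN_CARRIER_COUNTS",
    "FAMILY_BURDEN_COUNTS",
    "PATHWAY_TABLES",
    "pathway_gene_sets",
    "fance_family",
    "family_cohort",
]

# case allele count (of 2n = 238) and local-control allele count (of 2n = 2674)
_DISCOVERY_COUNTS: dict[str, tuple[int, int]] = {
    "JAK2": (9, 20),
    "APOB": (2, 0),
    "FAT3": (2, 0),
    "PRDM16": (3, 1),
    "BMPR1A": (3, 2),
    "IL21R": (2, 0),
    "N4BP2": (2, 0),
    "FLNA": (4, 3),
    "KMT2C": (2, 0),
    "ZEB1": (2, 0),
    "FAT4": (2, 0),
    "FANCE": (2, 0),
    "MPL": (2, 0),
    "LRP1B": (2, 0),
    "NIN": (2, 0),
    "NKX2-1": (2, 0),
    "CD28": (2, 0),
}

DISCOVERY_ALLELE_TABLES: dict[str, ContingencyTable] = {
    gene: ContingencyTable(a, 238 - a, c, 2674 - c, "allele")
    for gene, (a, c) in _DISCOVERY_COUNTS.items()
}

# validation cohort: (case ac, case an, control ac, control an); variants
# unobserved in the validation control cohort carry no entry
_VALIDATION_COUNTS: dict[str, tuple[int, int, int, int]] = {
    "JAK2": (5, 312, 180, 19178),
    "FAT3": (0, 312, 109, 19068),
    "PRDM16": (1, 312, 40, 18760),
    "BMPR1A": (0, 312, 5, 19048),
    "IL21R": (0, 312, 16, 18962),
    "N4BP2": (0, 312, 173, 19110),
    "FLNA": (0, 312, 14, 13534),
    "KMT2C": (0, 312, 5, 19106),
    "FAT4": (0, 312, 5, 19210),
    "FANCE": (0, 312, 16, 18978),
    "MPL": (0, 312, 5, 19024),
    "LRP1B": (1, 312, 27, 19236),
    "NIN": (2, 312, 60, 19098),
    "NKX2-1": (1, 312, 5, 18862),
    "CD28": (0, 312, 11, 18986),
}

VALIDATION_ALLELE_TABLES: dict[str, ContingencyTable] = {
    gene: ContingencyTable(a, an_case - a, c, an_ctrl - c, "allele")
    for gene, (a, an_case, c, an_ctrl) in _VALIDATION_COUNTS.items()
}

#: gene -> (case carriers of 119, control carriers of 1337) in the discovery
#: burden test
BURDEN_CARRIER_COUNTS: dict[str, tuple[int, int]] = {
    "JAK2": (9, 32),
    "APOB": (8, 46),
    "FAT3": (11, 101),
    "PRDM16": (5, 42),
    "BMPR1A": (5, 7),
    "IL21R": (2, 2),
    "N4BP2": (2, 33),
    "FLNA": (3, 41),
    "KMT2C": (6, 56),
    "ZEB1": (2, 12),
    "FAT4": (16, 121),
    "FANCE": (3, 8),
    "MPL": (0, 10),
    "LRP1B": (10, 107),
    "NIN": (7, 68),
    "NKX2-1": (2, 0),
    "CD28": (3, 1),
}

#: gene -> (affected carriers of 18, unaffected carriers of 36) in the family
#: burden test (16 probands + 2 affected relatives vs 36 unaffected relatives)
FAMILY_BURDEN_COUNTS: dict[str, tuple[int, int]] = {
    "JAK2": (0, 1),
    "APOB": (18, 36),
    "FAT3": (4, 8),
    "PRDM16": (2, 6),
    "BMPR1A": (1, 2),
    "IL21R": (0, 0),
    "N4BP2": (1, 1),
    "FLNA": (1, 4),
    "KMT2C": (18, 36),
    "ZEB1": (0, 0),
    "FAT4": (15, 34),
    "FANCE": (2, 0),
    "MPL": (0, 0),
    "LRP1B": (1, 2),
    "NIN": (13, 26),
    "NKX2-1": (0, 0),
    "CD28": (0, 0),
}

# pathway name -> (member genes, case carriers of 119, control carriers of 1337)
_PATHWAYS: dict[str, tuple[tuple[str, ...], int, int]] = {
    "GM-CSF Signalling": (
        ("CAMK2D", "CSF2RA", "GRB2", "JAK2", "PPP3CC", "RALB"),
        17,
        41,
    ),
    "Synaptogenesis Signalling Pathway": (
        ("ACTR3", "AP2A2", "CACNB2", "CAMK2D", "CDH8", "CREB1", "CTNNB1",
         "EFNA2", "GRB2", "NAP1L1", "NSF", "RAB5B", "RALB", "SHF", "SYT7"),
        29,
        61,
    ),
    "Clathrin-mediated Endocytosis Signalling": (
        ("ACTA1", "ACTR3", "AP2A2", "EPS15", "GRB2", "IGF1", "ORM1", "ORM2",
         "PPP3CC", "RAB5B"),
        19,
        25,
    ),
    "Role of JAK1 and JAK3 in gamma-c Cytokine Signalling": (
        ("GRB2", "IL15", "IL21R", "JAK2", "RALB"),
        16,
        41,
    ),
    "Agrin Interactions at Neuromuscular Junction": (
        ("ACTA1", "LAMA2", "NRG3", "PAK4", "RALB"),
        29,
        127,
    ),
    "NAD biosynthesis II (from tryptophan)": (("AFMID", "NMNAT3"), 5, 6),
    "Tryptophan Degradation III (Eukaryotic)": (
        ("AFMID", "HADHA", "L3HYPDH"),
        9,
        22,
    ),
    "CREB Signalling in Neurons": (
        ("ADGRB1", "ADORA2B", "ADRA1A", "BMPR1A", "BMPR1B", "CACNB2", "CAMK2D",
         "CREB1", "DRD1", "DRD3", "FFAR2", "GHRHR", "GLP2R", "GPR108", "GPR27",
         "GPR63", "GRB2", "IGF1", "PDGFRA", "PTGER1", "RALB", "RXFP1", "SSTR3"),
        57,
        160,
    ),
    "IL-15 Production": (
        ("CSF2RA", "DSTYK", "IL15", "JAK2", "PDGFRA", "TNK1", "ZAP70"),
        30,
        88,
    ),
    "Caveolar-mediated Endocytosis Signalling": (
        ("ACTA1", "CAVIN1", "FLOT2", "HLA-E", "RAB5B"),
        6,
        1,
    ),
}

PATHWAY_TABLES: dict[str, ContingencyTable] = {
    name: ContingencyTable(a, 119 - a, c, 1337 - c, "carrier")
    for name, (_, a, c) in _PATHWAYS.items()
}


def pathway_gene_sets() -> list[GeneSet]:
    """The ten implicated pathways with their listed member genes."""
    return [
        GeneSet(name=name, genes=frozenset(genes), description="implicated pathway")
        for name, (genes, _, _) in _PATHWAYS.items()
    ]


#: variant key of the FANCE c.1333C>T (p.P445S) candidate on chromosome 6
FANCE_VARIANT: VariantKey = ("6", 35425687, "C", "T")


def fance_family() -> tuple[Pedigree, dict[str, bool]]:
    """The five-sibling family: 2 affected carriers, 3 unaffected non-carriers.

    Parents are in the pedigree but ungenotyped (no carrier entry), matching
    how the family was reported; sibling ids are synthetic.
    """
    father, mother = "FAM_FANCE_F", "FAM_FANCE_M"
    members = [
        PedigreeMember(father, None, None, "male", False),
        PedigreeMember(mother, None, None, "female", False),
    ]
    carriers: dict[str, bool] = {}
    for i in range(5):
        sid = f"FAM_FANCE_S{i + 1}"
        affected = i < 2
        members.append(PedigreeMember(sid, father, mother, "unknown", affected))
        carriers[sid] = affected  # carriers are exactly the affected siblings
    return Pedigree(family_id="FAM_FANCE", members=members), carriers


def family_cohort() -> tuple[CarrierMatrix, dict[str, list[VariantKey]]]:
    """Synthetic 54-member family cohort reproducing the published counts.

    18 affected (16 probands + 2 affected relatives) and 36 unaffected
    members; per gene, one representative qualifying variant whose carriers
    are assigned deterministically so the per-gene (affected, unaffected)
    carrier counts equal the published family burden counts.  Returns the
    carrier matrix and the gene -> qualifying-variant mapping.
    """
    n_aff, n_unaff = 18, 36
    sample_ids = [f"case_fam{i:02d}" for i in range(n_aff)] + [
        f"ctrl_fam{i:02d}" for i in range(n_unaff)
    ]
    phen = ["case"] * n_aff + ["control"] * n_unaff
    genes = sorted(FAMILY_BURDEN_COUNTS)
    keys: list[VariantKey] = []
    dosage = np.zeros((n_aff + n_unaff, len(genes)), dtype=np.int8)
    qualifying: dict[str, list[VariantKey]] = {}
    for j, gene in enumerate(genes):
        key: VariantKey = ("1", 1000 + j, "A", "G")
        keys.append(key)
        qualifying[gene] = [key]
        aff_c, unaff_c = FAMILY_BURDEN_COUNTS[gene]
        dosage[:aff_c, j] = 1
        dosage[n_aff : n_aff + unaff_c, j] = 1
    matrix = CarrierMatrix(
        sample_ids=sample_ids, variant_keys=keys, dosage=dosage, phenotype=phen
    )
    return matrix, qualifying
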
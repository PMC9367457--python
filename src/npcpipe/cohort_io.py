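"""Domain types and readers/writers for the on-disk formats the pipeline touches.

The pipeline consumes called, annotated, QC-flagged variants; it never touches
reads or computes annotations.  Everything on disk is plain text: annotated
variant tables (tab-separated, ANNOVAR-style columns), cohort genotypes (VCF),
pedigrees (6-column PED), gene sets (GMT) and per-variant per-cohort mean-depth
tables (TSV).

Conventions
-----------
* Coordinates are 1-based and fully closed, matching VCF; distance between two
  sites is ``|pos_a - pos_b|`` on this convention.
* Multi-allelic VCF sites are split into biallelic records at read time; the
  dosage of a record counts only its own alternate allele.
* Missing genotypes (``./.``) count as non-carriers (dosage 0) but are tallied
  on the returned matrix, because carrier tests need a complete matrix.
* Gene symbols are compared case-sensitively after whitespace trimming; no
  alias resolution.
* Readers reject rather than silently coerce: the invariants documented on the
  types are enforced at read time, and write-then-read is the identity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "FuncClass",
    "LOF_CLASSES",
    "VariantKey",
    "AnnotatedVariant",
    "CarrierMatrix",
    "CohortAlleleCounts",
    "DepthRecord",
    "GeneSet",
    "PedigreeMember",
    "Pedigree",
    "read_annotated_variants",
    "write_annotated_variants",
    "read_genotypes_vcf",
    "write_genotypes_vcf",
    "read_gene_sets_gmt",
    "write_gene_sets_gmt",
    "read_pedigree_ped",
    "write_pedigree_ped",
    "read_depth_table",
    "write_depth_table",
    "read_panel_counts",
    "write_panel_counts",
]


class FormatError(ValueError):
    """An input file violates its declared format or a type invariant."""


class FuncClass(str, Enum):
    """Functional consequence classes the filtering cascade distinguishes."""

    NONSYNONYMOUS_SNV = "nonsynonymous_snv"
    FRAMESHIFT_INDEL = "frameshift_indel"
    STOPGAIN = "stopgain"
    STOPLOSS = "stoploss"
    STARTLOSS = "startloss"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


#: Loss-of-function classes: presumed to abolish protein function and retained
#: by the pathogenicity filter regardless of CADD score.
LOF_CLASSES = frozenset(
    {
        FuncClass.FRAMESHIFT_INDEL,
        FuncClass.STOPGAIN,
        FuncClass.STOPLOSS,
        FuncClass.STARTLOSS,
    }
)

#: (chrom, pos, ref, alt) — the identity of a biallelic variant record.
VariantKey = tuple[str, int, str, str]

_ALLELE_CHARS = set("ACGT")


@dataclass(frozen=True)
class AnnotatedVariant:
    """One called, annotated germline variant.

    ``maf_local`` and ``gnomad_af`` are the frequencies of the alternate allele
    in the local control cohort and the external reference panel; ``None``
    means the variant has no record there (which is *not* the same as
    frequency zero — a panel-absent variant may still be testable through
    allele-number interpolation).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    func_class: FuncClass
    cadd_phred: float
    maf_local: Optional[float] = None
    gnomad_af: Optional[float] = None
    gnomad_an: Optional[int] = None
    transcript_hgvs: Optional[str] = None
    rsid: Optional[str] = None
    clinvar: Optional[str] = None
    qc_pass: bool = True
    igv_excluded: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise FormatError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise FormatError("ref and alt alleles must be non-empty")
        if self.ref == self.alt:
            raise FormatError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        for allele in (self.ref, self.alt):
            if not (set(allele) <= _ALLELE_CHARS or allele in {"-", "*"}):
                raise FormatError(f"allele {allele!r} is not ACGT/indel form")
        if self.cadd_phred < 0:
            raise FormatError(f"cadd_phred must be >= 0, got {self.cadd_phred}")
        for name in ("maf_local", "gnomad_af"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise FormatError(f"{name}={v} outside [0, 1]")
        if self.gnomad_an is not None:
            if self.gnomad_an <= 0 or self.gnomad_an % 2:
                raise FormatError(
                    f"gnomad_an must be a positive even integer, got {self.gnomad_an}"
                )

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_lof(self) -> bool:
        return self.func_class in LOF_CLASSES


@dataclass
class CarrierMatrix:
    """Per-individual × per-variant allele dosages for one cohort.

    ``dosage[i, j]`` is the number of alternate alleles (0, 1 or 2) sample
    ``i`` carries at variant ``j``; an individual is a *carrier* of a variant
    iff dosage >= 1.  ``phenotype`` holds ``"case"`` / ``"control"`` labels.
    """

    sample_ids: list[str]
    variant_keys: list[VariantKey]
    dosage: np.ndarray
    phenotype: list[str]
    missing_genotypes: int = 0

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.sample_ids), len(self.variant_keys)):
            raise FormatError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.sample_ids)} samples × {len(self.variant_keys)} variants"
            )
        if len(self.phenotype) != len(self.sample_ids):
            raise FormatError("phenotype length does not match sample count")
        bad = set(self.phenotype) - {"case", "control"}
        if bad:
            raise FormatError(f"unknown phenotype labels: {sorted(bad)}")
        if self.dosage.size and (self.dosage.min() < 0 or self.dosage.max() > 2):
            raise FormatError("dosages must lie in {0, 1, 2}")
        self._vindex = {k: j for j, k in enumerate(self.variant_keys)}
        if len(self._vindex) != len(self.variant_keys):
            raise FormatError("duplicate variant keys in matrix")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_keys)

    @property
    def case_mask(self) -> np.ndarray:
        return np.array([p == "case" for p in self.phenotype], dtype=bool)

    @property
    def n_cases(self) -> int:
        return int(self.case_mask.sum())

    @property
    def n_controls(self) -> int:
        return self.n_samples - self.n_cases

    def variant_index(self, key: VariantKey) -> int:
        try:
            return self._vindex[key]
        except KeyError:
            raise KeyError(f"variant {key} not in carrier matrix") from None

    def carriers(self, key: VariantKey) -> np.ndarray:
        """Boolean per-sample carrier indicator for one variant."""
        return self.dosage[:, self.variant_index(key)] >= 1

    def case_carrier_count(self, key: VariantKey) -> int:
        return int((self.carriers(key) & self.case_mask).sum())

    def control_carrier_count(self, key: VariantKey) -> int:
        return int((self.carriers(key) & ~self.case_mask).sum())

    def allele_counts(self, key: VariantKey, group: str) -> tuple[int, int]:
        """(alternate-allele count, allele number) for ``group`` ∈ {case, control}."""
        mask = self.case_mask if group == "case" else ~self.case_mask
        ac = int(self.dosage[mask, self.variant_index(key)].sum())
        an = 2 * int(mask.sum())
        return ac, an

    def subset_variants(self, keys: Sequence[VariantKey]) -> "CarrierMatrix":
        idx = [self.variant_index(k) for k in keys]
        return CarrierMatrix(
            sample_ids=list(self.sample_ids),
            variant_keys=list(keys),
            dosage=self.dosage[:, idx].copy(),
            phenotype=list(self.phenotype),
            missing_genotypes=self.missing_genotypes,
        )


@dataclass(frozen=True)
class CohortAlleleCounts:
    """Allele count / allele number at one site in one cohort."""

    ac: int
    an: int
    cohort_label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.ac <= self.an):
            raise FormatError(f"require 0 <= ac <= an, got ac={self.ac}, an={self.an}")

    @property
    def af(self) -> float:
        return self.ac / self.an


@dataclass(frozen=True)
class DepthRecord:
    """Mean sequencing depth of one variant in one cohort (reads per sample)."""

    variant_key: VariantKey
    cohort_label: str
    mean_depth: float

    def __post_init__(self) -> None:
        if self.mean_depth < 0:
            raise FormatError(f"mean_depth must be >= 0, got {self.mean_depth}")


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise FormatError(f"gene set {self.name!r} is empty")

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


@dataclass(frozen=True)
class PedigreeMember:
    sample_id: str
    father_id: Optional[str]
    mother_id: Optional[str]
    sex: str  # "male" / "female" / "unknown"
    affected: bool


@dataclass
class Pedigree:
    family_id: str
    members: list[PedigreeMember]

    def __post_init__(self) -> None:
        ids = {m.sample_id for m in self.members}
        if len(ids) != len(self.members):
            raise FormatError(f"duplicate sample ids in family {self.family_id}")
        for m in self.members:
            for parent in (m.father_id, m.mother_id):
                if parent is not None and parent not in ids:
                    warnings.warn(
                        f"family {self.family_id}: parent {parent} of "
                        f"{m.sample_id} not in pedigree",
                        stacklevel=2,
                    )

    @property
    def affected_ids(self) -> list[str]:
        return [m.sample_id for m in self.members if m.affected]

    @property
    def unaffected_ids(self) -> list[str]:
        return [m.sample_id for m in self.members if not m.affected]


# ---------------------------------------------------------------------------
# Annotated variant tables (TSV)
# ---------------------------------------------------------------------------

#: field name -> default column header
DEFAULT_VARIANT_DIALECT: dict[str, str] = {
    "chrom": "chrom",
    "pos": "pos",
    "ref": "ref",
    "alt": "alt",
    "gene": "gene",
    "func_class": "func_class",
    "cadd_phred": "cadd_phred",
    "maf_local": "maf_local",
    "gnomad_af": "gnomad_af",
    "gnomad_an": "gnomad_an",
    "transcript_hgvs": "transcript_hgvs",
    "rsid": "rsid",
    "clinvar": "clinvar",
    "qc_pass": "qc_pass",
    "igv_excluded": "igv_excluded",
}

_REQUIRED_FIELDS = ("chrom", "pos", "ref", "alt", "gene", "func_class", "cadd_phred")
_MISSING_TOKENS = {"", ".", "NA", "N/A", "nan"}


def _parse_optional_float(cell: str, line_no: int, col: str) -> Optional[float]:
    if cell.strip() in _MISSING_TOKENS:
        return None
    try:
        return float(cell)
    except ValueError:
        raise FormatError(f"line {line_no}: cannot parse {col}={cell!r} as number") from None


def _parse_bool(cell: str, default: bool) -> bool:
    cell = cell.strip()
    if cell in _MISSING_TOKENS:
        return default
    return cell.lower() in {"1", "true", "yes", "t"}


def read_annotated_variants(
    path: str, dialect: Optional[Mapping[str, str]] = None
) -> list[AnnotatedVariant]:
    """Read a tab-separated annotated variant table.

    ``dialect`` maps :class:`AnnotatedVariant` field names to column headers
    in the file (defaults to the identity mapping of
    ``DEFAULT_VARIANT_DIALECT``).  Blank / ``.`` / ``NA`` frequency cells
    become missing values, never zero.
    """
    cols = dict(DEFAULT_VARIANT_DIALECT)
    if dialect:
        cols.update(dialect)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for field_name in _REQUIRED_FIELDS:
        if cols[field_name] not in df.columns:
            raise FormatError(
                f"{path}: missing required column {cols[field_name]!r} "
                f"(field {field_name})"
            )

    def cell(row: pd.Series, field_name: str) -> str:
        col = cols[field_name]
        return str(row[col]) if col in df.columns else ""

    variants: list[AnnotatedVariant] = []
    for i, row in df.iterrows():
        line_no = int(i) + 2  # header is line 1
        try:
            pos = int(cell(row, "pos"))
        except ValueError:
            raise FormatError(
                f"line {line_no}: cannot parse pos={cell(row, 'pos')!r} as integer"
            ) from None
        try:
            func_class = FuncClass(cell(row, "func_class").strip())
        except ValueError:
            raise FormatError(
                f"line {line_no}: unknown func_class {cell(row, 'func_class')!r}"
            ) from None
        cadd = _parse_optional_float(cell(row, "cadd_phred"), line_no, "cadd_phred")
        if cadd is None:
            raise FormatError(f"line {line_no}: cadd_phred is required")
        gnomad_an_cell = cell(row, "gnomad_an").strip()
        if gnomad_an_cell in _MISSING_TOKENS:
            gnomad_an = None
        else:
            try:
                gnomad_an = int(float(gnomad_an_cell))
            except ValueError:
                raise FormatError(
                    f"line {line_no}: cannot parse gnomad_an={gnomad_an_cell!r}"
                ) from None
        try:
            variants.append(
                AnnotatedVariant(
                    chrom=cell(row, "chrom").strip(),
                    pos=pos,
                    ref=cell(row, "ref").strip(),
                    alt=cell(row, "alt").strip(),
                    gene=cell(row, "gene").strip(),
                    func_class=func_class,
                    cadd_phred=cadd,
                    maf_local=_parse_optional_float(cell(row, "maf_local"), line_no, "maf_local"),
                    gnomad_af=_parse_optional_float(cell(row, "gnomad_af"), line_no, "gnomad_af"),
                    gnomad_an=gnomad_an,
                    transcript_hgvs=cell(row, "transcript_hgvs").strip() or None,
                    rsid=cell(row, "rsid").strip() or None,
                    clinvar=cell(row, "clinvar").strip() or None,
                    qc_pass=_parse_bool(cell(row, "qc_pass"), True),
                    igv_excluded=_parse_bool(cell(row, "igv_excluded"), False),
                )
            )
        except FormatError as exc:
            raise FormatError(f"line {line_no}: {exc}") from None
    return variants


def write_annotated_variants(variants: Iterable[AnnotatedVariant], path: str) -> None:
    rows = []
    for v in variants:
        rows.append(
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "gene": v.gene,
                "func_class": v.func_class.value,
                "cadd_phred": repr(float(v.cadd_phred)),
                "maf_local": "" if v.maf_local is None else repr(float(v.maf_local)),
                "gnomad_af": "" if v.gnomad_af is None else repr(float(v.gnomad_af)),
                "gnomad_an": "" if v.gnomad_an is None else int(v.gnomad_an),
                "transcript_hgvs": v.transcript_hgvs or "",
                "rsid": v.rsid or "",
                "clinvar": v.clinvar or "",
                "qc_pass": int(v.qc_pass),
                "igv_excluded": int(v.igv_excluded),
            }
        )
    pd.DataFrame(rows, columns=list(DEFAULT_VARIANT_DIALECT.values())).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# VCF genotypes
# ---------------------------------------------------------------------------


def read_genotypes_vcf(
    path: str, phenotypes: Optional[Mapping[str, str]] = None
) -> CarrierMatrix:
    """Read a VCF into a :class:`CarrierMatrix`.

    Multi-allelic sites are split into one biallelic record per alternate
    allele; a record's dosage counts only its own alternate.  Missing
    genotypes become dosage 0 and are tallied in ``missing_genotypes``.

    ``phenotypes`` maps sample id -> ``"case"`` / ``"control"``.  When absent,
    samples whose id starts with ``"case"`` are cases and all others controls
    (the convention the synthetic-cohort writer uses).
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad input
        raise FormatError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    if phenotypes is None:
        phen = ["case" if s.startswith("case") else "control" for s in samples]
    else:
        phen = [phenotypes.get(s, "control") for s in samples]

    keys: list[VariantKey] = []
    columns: list[np.ndarray] = []
    n_missing = 0
    for record in vcf:
        gts = record.genotypes  # [[a0, a1, phased], ...]
        for alt_idx, alt in enumerate(record.ALT, start=1):
            dos = np.zeros(len(samples), dtype=np.int8)
            for i, gt in enumerate(gts):
                alleles = gt[:-1]
                if any(a < 0 for a in alleles):
                    n_missing += 1
                    continue
                dos[i] = sum(1 for a in alleles if a == alt_idx)
            keys.append((str(record.CHROM), int(record.POS), str(record.REF), str(alt)))
            columns.append(dos)
    vcf.close()
    if n_missing:
        logger.info("read_genotypes_vcf(%s): %d missing genotypes set to dosage 0", path, n_missing)
    dosage = (
        np.stack(columns, axis=1) if columns else np.zeros((len(samples), 0), dtype=np.int8)
    )
    return CarrierMatrix(
        sample_ids=samples,
        variant_keys=keys,
        dosage=dosage,
        phenotype=phen,
        missing_genotypes=n_missing,
    )


def write_genotypes_vcf(matrix: CarrierMatrix, path: str) -> None:
    """Write a minimal biallelic VCF 4.2 with GT fields only."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chroms = {k[0] for k in matrix.variant_keys}
        for chrom in sorted(chroms):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.sample_ids)
            + "\n"
        )
        order = sorted(range(matrix.n_variants), key=lambda j: matrix.variant_keys[j][:2])
        gt_text = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j in order:
            chrom, pos, ref, alt = matrix.variant_keys[j]
            gts = "\t".join(gt_text[int(d)] for d in matrix.dosage[:, j])
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def read_gene_sets_gmt(path: str) -> list[GeneSet]:
    """Read a GMT file: ``name <tab> description <tab> gene1 <tab> gene2 ...``"""
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path} line {line_no}: GMT line needs name, description "
                    f"and at least one gene"
                )
            name = parts[0].strip()
            if name in seen:
                raise FormatError(f"{path} line {line_no}: duplicate gene-set name {name!r}")
            seen.add(name)
            genes = frozenset(g.strip() for g in parts[2:] if g.strip())
            sets.append(GeneSet(name=name, genes=genes, description=parts[1].strip()))
    return sets


def write_gene_sets_gmt(sets: Iterable[GeneSet], path: str) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *sorted(s.genes)]) + "\n")


# ---------------------------------------------------------------------------
# PED pedigrees
# ---------------------------------------------------------------------------

_SEX_CODE = {"1": "male", "2": "female"}
_SEX_TEXT = {"male": "1", "female": "2", "unknown": "0"}


def read_pedigree_ped(path: str) -> list[Pedigree]:
    """Read a 6-column PED file (family, id, father, mother, sex, phenotype).

    Phenotype code 2 means affected; 1 / 0 / -9 mean unaffected or unknown
    (treated as unaffected for co-segregation counting).  Parent id 0 means
    absent.
    """
    families: dict[str, list[PedigreeMember]] = {}
    order: list[str] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise FormatError(f"{path} line {line_no}: PED rows need >= 6 columns")
            fam, sid, father, mother, sex, phen = parts[:6]
            member = PedigreeMember(
                sample_id=sid,
                father_id=None if father == "0" else father,
                mother_id=None if mother == "0" else mother,
                sex=_SEX_CODE.get(sex, "unknown"),
                affected=(phen == "2"),
            )
            if fam not in families:
                families[fam] = []
                order.append(fam)
            families[fam].append(member)
    return [Pedigree(family_id=f, members=families[f]) for f in order]


def write_pedigree_ped(pedigrees: Iterable[Pedigree], path: str) -> None:
    with open(path, "w") as fh:
        for ped in pedigrees:
            for m in ped.members:
                fh.write(
                    "\t".join(
                        [
                            ped.family_id,
                            m.sample_id,
                            m.father_id or "0",
                            m.mother_id or "0",
                            _SEX_TEXT.get(m.sex, "0"),
                            "2" if m.affected else "1",
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# Depth tables
# ---------------------------------------------------------------------------


def read_depth_table(path: str) -> list[DepthRecord]:
    """TSV with columns chrom, pos, ref, alt, cohort, mean_depth."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["chrom", "pos", "ref", "alt", "cohort", "mean_depth"]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    records: list[DepthRecord] = []
    for i, row in df.iterrows():
        line_no = int(i) + 2
        try:
            pos = int(row["pos"])
            depth = float(row["mean_depth"])
        except ValueError:
            raise FormatError(f"{path} line {line_no}: unparseable pos/mean_depth") from None
        records.append(
            DepthRecord(
                variant_key=(row["chrom"], pos, row["ref"], row["alt"]),
                cohort_label=row["cohort"],
                mean_depth=depth,
            )
        )
    return records


def read_panel_counts(path: str) -> dict[VariantKey, CohortAlleleCounts]:
    """Reference-panel allele counts: TSV with chrom, pos, ref, alt, ac, an."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("chrom", "pos", "ref", "alt", "ac", "an"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    counts: dict[VariantKey, CohortAlleleCounts] = {}
    for i, row in df.iterrows():
        try:
            key = (row["chrom"], int(row["pos"]), row["ref"], row["alt"])
            cac = CohortAlleleCounts(
                ac=int(row["ac"]),
                an=int(row["an"]),
                cohort_label=str(row.get("cohort", "panel")),
            )
        except ValueError:
            raise FormatError(f"{path} line {int(i) + 2}: unparseable counts") from None
        counts[key] = cac
    return counts


def write_panel_counts(counts: Mapping[VariantKey, CohortAlleleCounts], path: str) -> None:
    rows = [
        {"chrom": k[0], "pos": k[1], "ref": k[2], "alt": k[3], "ac": c.ac, "an": c.an}
        for k, c in counts.items()
    ]
    pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "ac", "an"]).to_csv(
        path, sep="\t", index=False
    )


def write_depth_table(records: Iterable[DepthRecord], path: str) -> None:
    rows = [
        {
            "chrom": r.variant_key[0],
            "pos": r.variant_key[1],
            "ref": r.variant_key[2],
            "alt": r.variant_key[3],
            "cohort": r.cohort_label,
            "mean_depth": repr(float(r.mean_depth)),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "cohort", "mean_depth"]).to_csv(
        path, sep="\t", index=False
    )
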
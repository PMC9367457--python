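"""End-to-end orchestration of the rare-variant predisposition analysis.

Stage order: prioritization cascade → dual-cohort variant association
(discovery cases vs local controls, and vs the external reference panel) →
FDR shortlist → validation-cohort re-test of the shortlist → gene burden scan
with depth-cutoff selection → pathway analysis → family co-segregation.
Each stage's output is written as a self-describing TSV before the next stage
begins; a JSON run manifest mirrors the per-stage variant counts.  The
pipeline never mutates its inputs, and a rerun with identical inputs and
configuration produces byte-identical outputs.

The validation re-test is a re-invocation of the association machinery on the
shortlisted variants only, reporting raw p-values — the shortlist is a fixed
hypothesis set, not a new testing family.
"""

from __future__ import annotations

import dataclasses
import json
import os
import warnings
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .association import (
    AssociationResult,
    associate_cohort,
    dual_cohort_shortlist,
    interpolate_allele_number,
)
from .burden import DepthFilterConfig, depth_filter, run_burden_scan, select_depth_cutoff
from .cohort_io import (
    AnnotatedVariant,
    CarrierMatrix,
    CohortAlleleCounts,
    VariantKey,
    read_annotated_variants,
    read_depth_table,
    read_gene_sets_gmt,
    read_genotypes_vcf,
    read_panel_counts,
    read_pedigree_ped,
)
from .pathway import run_pathway_analysis
from .prioritization import CascadeConfig, run_cascade, variant_qualifies
from .segregation import segregation_check

__all__ = ["RunConfig", "RunManifest", "run_pipeline"]


@dataclass
class RunConfig:
    """Paths and knobs for one pipeline run; loadable from YAML."""

    variants_path: str
    discovery_vcf: str
    out_dir: str
    panel_path: Optional[str] = None
    validation_vcf: Optional[str] = None
    depths_path: Optional[str] = None
    sources_gmt: Optional[str] = None
    pathways_gmt: Optional[str] = None
    ped_path: Optional[str] = None
    family_vcf: Optional[str] = None
    cascade: CascadeConfig = field(default_factory=CascadeConfig)
    q: float = 0.10
    pathway_alpha: float = 0.05
    pathway_universe: int = 20000
    depth: DepthFilterConfig = field(default_factory=DepthFilterConfig)
    depth_filtered_cohort: str = "control"
    conf_level: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.q < 1) or not (0 < self.pathway_alpha < 1):
            raise ValueError("q and pathway_alpha must lie in (0, 1)")
        for attr in ("variants_path", "discovery_vcf"):
            path = getattr(self, attr)
            if not os.path.exists(path):
                raise FileNotFoundError(f"{attr}: {path}")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cascade = CascadeConfig(**raw.pop("cascade", {}))
        depth = DepthFilterConfig(**raw.pop("depth", {}))
        return cls(cascade=cascade, depth=depth, **raw)


@dataclass
class RunManifest:
    config: dict
    version: str
    seed: int
    stage_counts: dict[str, int] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    failed_stage: Optional[str] = None

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")


def _config_echo(config: RunConfig) -> dict:
    echo = dataclasses.asdict(config)
    echo["cascade"]["lof_classes"] = sorted(
        c.value for c in config.cascade.lof_classes
    )
    echo["cascade"]["cancer_gene_sources"] = [
        s.name for s in config.cascade.cancer_gene_sources
    ]
    return echo


def _association_frame(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [r.variant_key[0] for r in results],
            "pos": [r.variant_key[1] for r in results],
            "ref": [r.variant_key[2] for r in results],
            "alt": [r.variant_key[3] for r in results],
            "case_af": [r.table.case_freq for r in results],
            "control_af": [r.table.control_freq for r in results],
            "odds_ratio": [r.or_estimate for r in results],
            "ci_low": [r.ci_low for r in results],
            "ci_high": [r.ci_high for r in results],
            "p_value": [r.p_raw for r in results],
            "p_fdr": [r.p_fdr for r in results],
            "comparison": [r.comparison_label for r in results],
        }
    )


def _allele_counts_from_matrix(
    matrix: CarrierMatrix, keys: list[VariantKey], group: str, label: str
) -> dict[VariantKey, CohortAlleleCounts]:
    out = {}
    for key in keys:
        ac, an = matrix.allele_counts(key, group)
        out[key] = CohortAlleleCounts(ac=ac, an=an, cohort_label=label)
    return out


def _panel_counts_for(
    variants: list[AnnotatedVariant],
    panel: dict[VariantKey, CohortAlleleCounts],
) -> dict[VariantKey, CohortAlleleCounts]:
    """Panel counts per variant; panel-absent sites get AC 0 with an
    interpolated allele number when a valid panel site lies within 300 nt."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for (chrom, pos, _, _), counts in panel.items():
        by_chrom.setdefault(chrom, []).append((pos, counts.an))
    for sites in by_chrom.values():
        sites.sort()
    out: dict[VariantKey, CohortAlleleCounts] = {}
    for v in variants:
        if v.key in panel:
            out[v.key] = panel[v.key]
            continue
        an = interpolate_allele_number(v.pos, by_chrom.get(v.chrom, []))
        if an is not None:
            out[v.key] = CohortAlleleCounts(ac=0, an=an, cohort_label="panel")
    return out


def run_pipeline(config: RunConfig) -> RunManifest:
    os.makedirs(config.out_dir, exist_ok=True)
    manifest = RunManifest(
        config=_config_echo(config), version=__version__, seed=config.seed
    )
    manifest_path = os.path.join(config.out_dir, "manifest.json")

    def out(name: str) -> str:
        path = os.path.join(config.out_dir, name)
        manifest.outputs[name.split(".")[0]] = path
        return path

    try:
        stage = "read_inputs"
        variants = read_annotated_variants(config.variants_path)
        genotypes = read_genotypes_vcf(config.discovery_vcf) if variants else None
        cascade = config.cascade
        if config.sources_gmt and not cascade.cancer_gene_sources:
            cascade = dataclasses.replace(
                cascade, cancer_gene_sources=read_gene_sets_gmt(config.sources_gmt)
            )
        manifest.stage_counts["input_variants"] = len(variants)

        stage = "prioritization"
        selected, report = run_cascade(variants, genotypes, cascade)
        manifest.stage_counts.update(
            pass_qc=report.total_pass_qc,
            recurrent=report.recurrent,
            rare=report.rare,
            pathogenic=report.pathogenic,
            selected=report.in_cancer_genes,
            singletons=report.n_singletons,
        )
        from .cohort_io import write_annotated_variants

        write_annotated_variants(selected, out("selected.tsv"))
        with open(out("cascade_report.json"), "w") as fh:
            json.dump(
                {
                    "counts": manifest.stage_counts,
                    "stage_of_elimination": {
                        "|".join(map(str, k)): s
                        for k, s in sorted(report.stage_of_elimination.items())
                    },
                },
                fh,
                indent=1,
                sort_keys=True,
            )
            fh.write("\n")

        stage = "association"
        shortlist: list[VariantKey] = []
        results_local: list[AssociationResult] = []
        if selected and genotypes is not None:
            keys = [v.key for v in selected]
            case_counts = _allele_counts_from_matrix(genotypes, keys, "case", "discovery")
            local_counts = _allele_counts_from_matrix(
                genotypes, keys, "control", "local_control"
            )
            results_local = associate_cohort(
                selected, case_counts, local_counts, "local", config.conf_level
            )
            _association_frame(results_local).to_csv(
                out("association_local.tsv"), sep="\t", index=False
            )
            if config.panel_path:
                panel = read_panel_counts(config.panel_path)
                panel_counts = _panel_counts_for(selected, panel)
                results_panel = associate_cohort(
                    selected, case_counts, panel_counts, "panel", config.conf_level
                )
                _association_frame(results_panel).to_csv(
                    out("association_panel.tsv"), sep="\t", index=False
                )
                shortlist = dual_cohort_shortlist(results_local, results_panel, config.q)
        manifest.stage_counts["shortlisted"] = len(shortlist)
        pd.DataFrame(
            shortlist, columns=["chrom", "pos", "ref", "alt"]
        ).to_csv(out("shortlist.tsv"), sep="\t", index=False)

        stage = "validation"
        if shortlist and config.validation_vcf:
            vmatrix = read_genotypes_vcf(config.validation_vcf)
            testable = [
                v
                for v in selected
                if v.key in shortlist and v.key in set(vmatrix.variant_keys)
            ]
            vcase = _allele_counts_from_matrix(
                vmatrix, [v.key for v in testable], "case", "validation"
            )
            vctrl = _allele_counts_from_matrix(
                vmatrix, [v.key for v in testable], "control", "validation_control"
            )
            results_val = associate_cohort(
                testable, vcase, vctrl, "validation", config.conf_level, adjust=False
            )
            _association_frame(results_val).to_csv(
                out("validation.tsv"), sep="\t", index=False
            )
            manifest.stage_counts["validation_tested"] = len(results_val)

        stage = "burden"
        burden_results = []
        qualifying: dict[str, list[VariantKey]] = {}
        if variants and genotypes is not None:
            burden_variants = [v for v in variants if variant_qualifies(v, cascade)]
            if config.depths_path:
                depths = read_depth_table(config.depths_path)
                if len(config.depth.candidate_cutoffs) > 1:
                    try:
                        cutoff, diagnostics = select_depth_cutoff(
                            config.depth.candidate_cutoffs,
                            burden_variants,
                            depths,
                            genotypes,
                            config.depth_filtered_cohort,
                            tolerance=config.depth.selection_tolerance,
                        )
                        pd.DataFrame(
                            [dataclasses.asdict(d) for d in diagnostics]
                        ).to_csv(out("depth_cutoff_scan.tsv"), sep="\t", index=False)
                    except ValueError:
                        # too few testable genes for a QQ-based choice: keep
                        # the most permissive candidate rather than aborting
                        cutoff = min(config.depth.candidate_cutoffs)
                        warnings.warn(
                            "depth-cutoff scan degenerate; "
                            f"falling back to cutoff {cutoff}"
                        )
                else:
                    cutoff = (
                        config.depth.candidate_cutoffs[0]
                        if config.depth.candidate_cutoffs
                        else 0.0
                    )
                manifest.stage_counts["depth_cutoff_x10"] = int(round(cutoff * 10))
                burden_variants = depth_filter(
                    burden_variants, depths, {config.depth_filtered_cohort: cutoff}
                )
            for v in burden_variants:
                qualifying.setdefault(v.gene, []).append(v.key)
            burden_results = run_burden_scan(genotypes, qualifying)
            pd.DataFrame(
                [dataclasses.asdict(r) for r in burden_results]
            ).to_csv(out("burden_genes.tsv"), sep="\t", index=False)
            manifest.stage_counts["burden_genes_tested"] = len(burden_results)

        stage = "pathway"
        if config.pathways_gmt and genotypes is not None and variants:
            pathways = read_gene_sets_gmt(config.pathways_gmt)
            # pathway scan drops the known-cancer-gene requirement
            open_cascade = dataclasses.replace(
                cascade, cancer_gene_sources=[]
            )
            open_qualifying: dict[str, list[VariantKey]] = {}
            for v in variants:
                if variant_qualifies(v, open_cascade):
                    open_qualifying.setdefault(v.gene, []).append(v.key)
            open_burden = run_burden_scan(genotypes, open_qualifying)
            pathway_results = run_pathway_analysis(
                pathways,
                open_burden,
                open_qualifying,
                genotypes,
                universe_size=config.pathway_universe,
                alpha=config.pathway_alpha,
                conf_level=config.conf_level,
            )
            pd.DataFrame(
                [dataclasses.asdict(r) for r in pathway_results]
            ).to_csv(out("pathways.tsv"), sep="\t", index=False)
            manifest.stage_counts["pathways_tested"] = len(pathway_results)

        stage = "segregation"
        if config.ped_path and config.family_vcf and shortlist:
            pedigrees = read_pedigree_ped(config.ped_path)
            fmatrix = read_genotypes_vcf(config.family_vcf)
            rows = []
            fkeys = set(fmatrix.variant_keys)
            for key in shortlist:
                if key not in fkeys:
                    continue
                carrier_vec = fmatrix.carriers(key)
                carrier_map = dict(zip(fmatrix.sample_ids, map(bool, carrier_vec)))
                for ped in pedigrees:
                    genotyped = {
                        m.sample_id: carrier_map[m.sample_id]
                        for m in ped.members
                        if m.sample_id in carrier_map
                    }
                    call = segregation_check(key, ped, genotyped)
                    rows.append(dataclasses.asdict(call))
            pd.DataFrame(rows).to_csv(out("segregation.tsv"), sep="\t", index=False)
            manifest.stage_counts["segregation_calls"] = len(rows)
    except Exception:
        manifest.failed_stage = stage
        manifest.write(manifest_path)
        raise
    manifest.write(manifest_path)
    return manifest
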
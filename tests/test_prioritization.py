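"""The four-stage filtering cascade: stage predicates, ordering, idempotence."""

import dataclasses

import numpy as np
import pytest

from npcpipe.cohort_io import (
    AnnotatedVariant,
    CarrierMatrix,
    FuncClass,
    GeneSet,
    LOF_CLASSES,
)
from npcpipe.prioritization import (
    CascadeConfig,
    run_cascade,
    stage_cancer_gene,
    stage_pathogenic,
    stage_rare,
    stage_recurrence,
    variant_qualifies,
)


def make_variant(pos=100, **overrides):
    base = dict(
        chrom="1", pos=pos, ref="A", alt="G", gene="JAK2",
        func_class=FuncClass.NONSYNONYMOUS_SNV, cadd_phred=25.0,
        maf_local=0.001, gnomad_af=0.001,
    )
    base.update(overrides)
    return AnnotatedVariant(**base)


def matrix_with_case_carriers(variants, carriers_per_variant, n_cases=5, n_controls=5):
    """Carrier matrix where variant j is carried by the first k_j cases."""
    n = n_cases + n_controls
    dosage = np.zeros((n, len(variants)), dtype=np.int8)
    for j, k in enumerate(carriers_per_variant):
        dosage[:k, j] = 1
    return CarrierMatrix(
        sample_ids=[f"s{i}" for i in range(n)],
        variant_keys=[v.key for v in variants],
        dosage=dosage,
        phenotype=["case"] * n_cases + ["control"] * n_controls,
    )


class TestStageRecurrence:
    def test_two_case_carriers_is_recurrent_one_is_singleton(self):
        variants = [make_variant(pos=p) for p in (100, 200, 300)]
        genotypes = matrix_with_case_carriers(variants, [2, 1, 0])
        recurrent, singletons = stage_recurrence(variants, genotypes)
        assert [v.pos for v in recurrent] == [100]
        assert [v.pos for v in singletons] == [200]

    def test_partitions_carried_variants_and_recounts(self, rng):
        variants = [make_variant(pos=100 + i) for i in range(50)]
        counts = [int(rng.integers(0, 5)) for _ in range(50)]
        genotypes = matrix_with_case_carriers(variants, counts)
        recurrent, singletons = stage_recurrence(variants, genotypes)
        rec_keys = {v.key for v in recurrent}
        sing_keys = {v.key for v in singletons}
        assert not rec_keys & sing_keys
        # brute-force recount straight from the dosage matrix
        case_rows = genotypes.dosage[genotypes.case_mask]
        for j, v in enumerate(variants):
            n = int((case_rows[:, j] >= 1).sum())
            assert (v.key in rec_keys) == (n >= 2)
            assert (v.key in sing_keys) == (n == 1)

    def test_variant_missing_from_matrix_is_an_error(self):
        variants = [make_variant(pos=100)]
        genotypes = matrix_with_case_carriers([make_variant(pos=999)], [1])
        with pytest.raises(KeyError):
            stage_recurrence(variants, genotypes)


class TestStageRare:
    def test_rare_in_both_panels_passes(self):
        assert stage_rare(make_variant(maf_local=0.005, gnomad_af=0.0009))

    def test_common_locally_fails(self):
        assert not stage_rare(make_variant(maf_local=0.02))

    def test_absent_from_panel_survives(self):
        # a variant unseen in all controls must not be disqualified
        assert stage_rare(make_variant(maf_local=0.0, gnomad_af=None))

    def test_threshold_is_strict(self):
        assert not stage_rare(make_variant(maf_local=0.01))


class TestStagePathogenic:
    def test_high_cadd_nonsynonymous_passes(self):
        assert stage_pathogenic(make_variant(cadd_phred=22.1))

    def test_cadd_exactly_at_threshold_fails(self):
        assert not stage_pathogenic(make_variant(cadd_phred=20.0))

    def test_lof_passes_regardless_of_cadd(self):
        assert stage_pathogenic(
            make_variant(func_class=FuncClass.STOPGAIN, cadd_phred=5.0)
        )

    @pytest.mark.parametrize("func_class", list(FuncClass))
    @pytest.mark.parametrize("cadd", [0.0, 19.9, 20.0, 20.1, 35.0])
    def test_rule_table_over_all_class_score_combinations(self, func_class, cadd):
        v = make_variant(func_class=func_class, cadd_phred=cadd)
        expected = (func_class in LOF_CLASSES) or (
            func_class is FuncClass.NONSYNONYMOUS_SNV and cadd > 20.0
        )
        assert stage_pathogenic(v) == expected


class TestStageCancerGene:
    SOURCES = [
        GeneSet(f"src{i}", frozenset(genes))
        for i, genes in enumerate(
            [{"JAK2", "APOB"}, {"JAK2", "NKX2-1"}, {"FANCE"}, {"FANCE"}, {"NKX2-1"}]
        )
    ]

    def test_gene_in_two_of_five_sources_passes(self):
        assert stage_cancer_gene("JAK2", self.SOURCES)
        assert stage_cancer_gene("FANCE", self.SOURCES)

    def test_gene_in_one_source_fails(self):
        assert not stage_cancer_gene("APOB", self.SOURCES)

    def test_counting_matches_brute_force_set_scan(self, rng):
        genes = [f"G{i}" for i in range(30)]
        sources = [
            GeneSet(f"s{j}", frozenset(g for g in genes if rng.random() < 0.3) or frozenset({"X"}))
            for j in range(5)
        ]
        for g in genes:
            want = sum(g in s.genes for s in sources) >= 2
            assert stage_cancer_gene(g, sources) == want

    def test_no_sources_is_an_error(self):
        with pytest.raises(ValueError):
            stage_cancer_gene("JAK2", [])


def brute_force_filter(variants, genotypes, config):
    """Independent re-implementation of the cascade as one flat predicate."""
    out = []
    for v in variants:
        if not v.qc_pass or v.igv_excluded:
            continue
        case_carriers = sum(
            1
            for i in range(genotypes.n_samples)
            if genotypes.phenotype[i] == "case"
            and genotypes.dosage[i, genotypes.variant_index(v.key)] >= 1
        )
        if case_carriers < config.min_case_carriers:
            continue
        if v.maf_local is not None and v.maf_local >= config.maf_threshold:
            continue
        if v.gnomad_af is not None and v.gnomad_af >= config.maf_threshold:
            continue
        lof = v.func_class in config.lof_classes
        patho = v.func_class == FuncClass.NONSYNONYMOUS_SNV and v.cadd_phred > config.cadd_threshold
        if not (lof or patho):
            continue
        if config.cancer_gene_sources:
            hits = sum(v.gene in s.genes for s in config.cancer_gene_sources)
            if hits < config.min_source_count:
                continue
        out.append(v.key)
    return out


class TestRunCascade:
    def test_empty_input_gives_empty_selection_and_zero_report(self):
        selected, report = run_cascade([], None, CascadeConfig())
        assert selected == []
        assert report.counts() == [0, 0, 0, 0, 0]

    def test_counts_monotone_and_match_brute_force(self, small_cohort):
        config_sim, sim, sources = small_cohort
        config = CascadeConfig(cancer_gene_sources=sources)
        selected, report = run_cascade(sim.variants, sim.genotypes, config)
        counts = report.counts()
        assert counts == sorted(counts, reverse=True)
        assert [v.key for v in selected] == brute_force_filter(
            sim.variants, sim.genotypes, config
        )

    def test_qc_failures_and_exclusions_dropped_first(self):
        variants = [
            make_variant(pos=100, qc_pass=False),
            make_variant(pos=200, igv_excluded=True),
            make_variant(pos=300),
        ]
        genotypes = matrix_with_case_carriers(variants, [3, 3, 3])
        selected, report = run_cascade(
            variants, genotypes, CascadeConfig(cancer_gene_sources=[])
        )
        assert report.total_pass_qc == 1
        assert [v.pos for v in selected] == [300]
        assert report.stage_of_elimination[variants[0].key] == "qc"

    def test_permissive_thresholds_select_all_recurrent(self, small_cohort):
        _, sim, _ = small_cohort
        config = CascadeConfig(
            maf_threshold=1.0, cadd_threshold=0.0,
            lof_classes=frozenset(FuncClass),  # every class counts as retained
            cancer_gene_sources=[],
        )
        selected, report = run_cascade(sim.variants, sim.genotypes, config)
        recurrent, _ = stage_recurrence(sim.variants, sim.genotypes)
        assert {v.key for v in selected} == {v.key for v in recurrent}

    def test_idempotent_on_its_own_output(self, small_cohort):
        _, sim, sources = small_cohort
        config = CascadeConfig(cancer_gene_sources=sources)
        selected, _ = run_cascade(sim.variants, sim.genotypes, config)
        again, _ = run_cascade(selected, sim.genotypes, config)
        assert [v.key for v in again] == [v.key for v in selected]

    def test_per_variant_predicates_commute(self, small_cohort):
        """rare/pathogenic/cancer-gene applied in any order give the same set."""
        _, sim, sources = small_cohort
        config = CascadeConfig(cancer_gene_sources=sources)
        recurrent, _ = stage_recurrence(sim.variants, sim.genotypes)
        recurrent = [v for v in recurrent if v.qc_pass and not v.igv_excluded]
        import itertools

        predicates = {
            "rare": lambda v: stage_rare(v, config.maf_threshold),
            "patho": lambda v: stage_pathogenic(v, config.cadd_threshold),
            "cancer": lambda v: stage_cancer_gene(v.gene, sources, 2),
        }
        reference = None
        for order in itertools.permutations(predicates):
            current = list(recurrent)
            for name in order:
                current = [v for v in current if predicates[name](v)]
            keys = {v.key for v in current}
            reference = keys if reference is None else reference
            assert keys == reference


def test_variant_qualifies_skips_recurrence_but_keeps_other_stages():
    sources = [GeneSet("a", frozenset({"JAK2"})), GeneSet("b", frozenset({"JAK2"}))]
    config = CascadeConfig(cancer_gene_sources=sources)
    assert variant_qualifies(make_variant(), config)
    assert not variant_qualifies(make_variant(maf_local=0.05), config)
    assert not variant_qualifies(make_variant(qc_pass=False), config)
    assert not variant_qualifies(make_variant(gene="OTHER"), config)


def test_cascade_config_validation():
    with pytest.raises(ValueError):
        CascadeConfig(min_case_carriers=0)
    with pytest.raises(ValueError):
        CascadeConfig(
            min_source_count=3,
            cancer_gene_sources=[GeneSet("a", frozenset({"X"}))],
        )
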
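"""Exact 2×2 inference, allele-number interpolation, BH, dual-cohort shortlist."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oracles import (
    bh_definitional,
    conditional_mle_or,
    exact_ci,
    fisher_p_enumeration,
    random_nondegenerate_table,
)

from npcpipe.association import (
    AssociationResult,
    ContingencyTable,
    associate_cohort,
    bh_adjust,
    dual_cohort_shortlist,
    fisher_two_tailed,
    interpolate_allele_number,
    odds_ratio_exact,
)
from npcpipe.cohort_io import AnnotatedVariant, CohortAlleleCounts, FuncClass
from npcpipe.datasets import DISCOVERY_ALLELE_TABLES, VALIDATION_ALLELE_TABLES


class TestFisherTwoTailed:
    @pytest.mark.parametrize(
        "table, expected",
        [
            # discovery comparison, reconstructed from printed allele frequencies
            (DISCOVERY_ALLELE_TABLES["JAK2"], 0.000327),
            (DISCOVERY_ALLELE_TABLES["APOB"], 0.00665),
            (DISCOVERY_ALLELE_TABLES["PRDM16"], 0.00203),
            # validation comparison, from explicitly printed counts
            (VALIDATION_ALLELE_TABLES["FAT3"], 0.426),
            (VALIDATION_ALLELE_TABLES["NKX2-1"], 0.0938),
        ],
    )
    def test_reference_cohort_p_values(self, table, expected):
        assert fisher_two_tailed(table) == pytest.approx(expected, rel=5e-3)

    def test_equal_exposure_proportions_give_p_one(self):
        assert fisher_two_tailed(ContingencyTable(1, 9, 1, 9)) == 1.0

    def test_empty_margin_is_an_error(self):
        with pytest.raises(ValueError):
            fisher_two_tailed(ContingencyTable(0, 5, 0, 7))

    def test_matches_exact_enumeration_on_random_tables(self, rng):
        for _ in range(300):
            a, b, c, d = random_nondegenerate_table(rng)
            p = fisher_two_tailed(ContingencyTable(a, b, c, d))
            assert p == pytest.approx(fisher_p_enumeration(a, b, c, d), abs=1e-12)

    def test_invariant_under_transposing_rows_and_columns(self, rng):
        for _ in range(50):
            a, b, c, d = random_nondegenerate_table(rng)
            p = fisher_two_tailed(ContingencyTable(a, b, c, d))
            assert fisher_two_tailed(ContingencyTable(a, c, b, d)) == pytest.approx(p, abs=1e-12)
            assert fisher_two_tailed(ContingencyTable(c, d, a, b)) == pytest.approx(p, abs=1e-12)


class TestOddsRatioExact:
    def test_zero_control_exposure_gives_infinite_estimate(self):
        est, lo, hi = odds_ratio_exact(DISCOVERY_ALLELE_TABLES["APOB"])
        assert est == math.inf and hi == math.inf
        assert lo == pytest.approx(2.1, abs=0.05)

    @pytest.mark.parametrize(
        "table, expected_or",
        [
            (DISCOVERY_ALLELE_TABLES["JAK2"], 5.2),
            (VALIDATION_ALLELE_TABLES["JAK2"], 1.7),
            (VALIDATION_ALLELE_TABLES["NIN"], 2.0),
            (VALIDATION_ALLELE_TABLES["NKX2-1"], 12.1),
        ],
    )
    def test_reference_cohort_estimates(self, table, expected_or):
        est, _, _ = odds_ratio_exact(table)
        assert round(est, 1) == expected_or

    def test_identical_rows_give_estimate_one(self):
        est, _, _ = odds_ratio_exact(ContingencyTable(3, 7, 3, 7))
        assert est == pytest.approx(1.0, abs=1e-9)

    def test_zero_case_exposure_gives_zero_estimate(self):
        est, lo, hi = odds_ratio_exact(VALIDATION_ALLELE_TABLES["FAT3"])
        assert est == 0.0 and lo == 0.0
        assert hi == pytest.approx(2.1, abs=0.05)

    def test_both_exposed_cells_zero_is_an_error(self):
        with pytest.raises(ValueError):
            odds_ratio_exact(ContingencyTable(0, 5, 0, 7))

    def test_matches_conditional_likelihood_oracle(self, rng):
        checked = 0
        while checked < 100:
            a, b, c, d = random_nondegenerate_table(rng)
            oracle_est = conditional_mle_or(a, b, c, d)
            if math.isnan(oracle_est):
                continue
            est, lo, hi = odds_ratio_exact(ContingencyTable(a, b, c, d))
            o_lo, o_hi = exact_ci(a, b, c, d)
            for got, want in [(est, oracle_est), (lo, o_lo), (hi, o_hi)]:
                if math.isinf(want):
                    assert math.isinf(got)
                else:
                    assert got == pytest.approx(want, rel=1e-9, abs=1e-12)
            checked += 1

    def test_estimate_lies_inside_its_confidence_interval(self, rng):
        for _ in range(100):
            a, b, c, d = random_nondegenerate_table(rng)
            est, lo, hi = odds_ratio_exact(ContingencyTable(a, b, c, d))
            assert lo <= est <= hi

    def test_swapping_case_control_inverts_the_estimate(self, rng):
        for _ in range(50):
            a, b, c, d = random_nondegenerate_table(rng)
            if min(a, b, c, d) == 0:
                continue
            est, _, _ = odds_ratio_exact(ContingencyTable(a, b, c, d))
            inv, _, _ = odds_ratio_exact(ContingencyTable(c, d, a, b))
            assert inv == pytest.approx(1.0 / est, rel=1e-8)

    def test_confidence_level_is_configurable(self):
        t = DISCOVERY_ALLELE_TABLES["JAK2"]
        _, lo95, hi95 = odds_ratio_exact(t, conf_level=0.95)
        _, lo90, hi90 = odds_ratio_exact(t, conf_level=0.90)
        assert lo95 < lo90 and hi90 < hi95


class TestInterpolateAlleleNumber:
    def test_midpoint_interpolates_linearly(self):
        assert interpolate_allele_number(1000, [(900, 1000), (1100, 2000)]) == 1500

    def test_nearest_site_beyond_window_gives_missing(self):
        assert interpolate_allele_number(1000, [(1301, 5000)]) is None

    def test_single_side_within_window_uses_that_site(self):
        assert interpolate_allele_number(1000, [(800, 4000)]) == 4000

    def test_exact_site_match_returns_its_an(self):
        assert interpolate_allele_number(900, [(900, 1234), (1000, 2000)]) == 1234

    def test_result_rounded_to_even(self):
        an = interpolate_allele_number(1001, [(1000, 1000), (1004, 1002)])
        assert an is not None and an % 2 == 0

    @given(st.integers(905, 1095))
    def test_monotone_between_two_fixed_neighbors(self, pos):
        sites = [(900, 1000), (1100, 3000)]
        an = interpolate_allele_number(pos, sites)
        an_next = interpolate_allele_number(pos + 1, sites)
        assert an is not None and an_next is not None
        assert 1000 <= an <= 3000
        assert an <= an_next

    def test_unsorted_sites_rejected(self):
        with pytest.raises(ValueError):
            interpolate_allele_number(1000, [(1100, 10), (900, 10)])


class TestBhAdjust:
    def test_single_p_is_identity(self):
        assert bh_adjust([0.03]) == [0.03]

    def test_equal_p_values_stay_equal(self):
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_matches_definitional_oracle(self, rng):
        for _ in range(50):
            p = rng.uniform(1e-6, 1.0, size=int(rng.integers(1, 40))).tolist()
            assert bh_adjust(p) == pytest.approx(bh_definitional(p), abs=1e-12)

    @given(st.permutations(range(6)))
    def test_invariant_to_input_permutation(self, perm):
        p = [0.001, 0.02, 0.02, 0.3, 0.7, 1.0]
        base = bh_adjust(p)
        shuffled = [p[i] for i in perm]
        adjusted = bh_adjust(shuffled)
        restored = [None] * len(p)
        for out_pos, in_pos in enumerate(perm):
            restored[in_pos] = adjusted[out_pos]
        assert restored == pytest.approx(base)

    def test_rejects_out_of_range_p(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])


def _result(key, a, b, c, d, p_fdr):
    t = ContingencyTable(a, b, c, d)
    return AssociationResult(key, t, 1.0, 0.5, 2.0, p_fdr, p_fdr, "x")


class TestDualCohortShortlist:
    def test_significant_in_both_comparisons_is_shortlisted(self):
        key = ("1", 100, "A", "G")
        local = [_result(key, 2, 236, 0, 2674, 0.0606)]
        panel = [_result(key, 2, 236, 5, 18857, 0.0497)]
        assert dual_cohort_shortlist(local, panel, q=0.10) == [key]

    def test_significant_in_one_comparison_is_not(self):
        key = ("1", 100, "A", "G")
        local = [_result(key, 2, 236, 0, 2674, 0.05)]
        panel = [_result(key, 2, 236, 5, 18857, 0.15)]
        assert dual_cohort_shortlist(local, panel, q=0.10) == []

    def test_direction_check_requires_case_excess(self):
        key = ("1", 100, "A", "G")
        # strongly significant but depleted in cases
        local = [_result(key, 0, 238, 100, 2574, 0.001)]
        panel = [_result(key, 0, 238, 900, 17952, 0.001)]
        assert dual_cohort_shortlist(local, panel, q=0.10) == []

    def test_key_in_one_list_only_warns_and_is_excluded(self):
        k1, k2 = ("1", 100, "A", "G"), ("1", 200, "C", "T")
        local = [_result(k1, 5, 233, 1, 2673, 0.01), _result(k2, 5, 233, 1, 2673, 0.01)]
        panel = [_result(k1, 5, 233, 1, 19251, 0.01)]
        with pytest.warns(UserWarning):
            assert dual_cohort_shortlist(local, panel) == [k1]

    def test_matches_brute_force_intersection(self, rng):
        keys = [("1", int(i), "A", "G") for i in range(1, 40)]
        local, panel = [], []
        for k in keys:
            a, c = int(rng.integers(0, 6)), int(rng.integers(0, 6))
            pl, pp = float(rng.uniform(0, 0.3)), float(rng.uniform(0, 0.3))
            local.append(_result(k, a, 100 - a, c, 1000 - c, pl))
            panel.append(_result(k, a, 100 - a, c, 1000 - c, pp))
        got = set(dual_cohort_shortlist(local, panel, q=0.10))
        want = set()
        for rl, rp in zip(local, panel):
            if (
                rl.p_fdr < 0.10
                and rp.p_fdr < 0.10
                and rl.table.case_freq > rl.table.control_freq
                and rp.table.case_freq > rp.table.control_freq
            ):
                want.add(rl.variant_key)
        assert got == want


class TestAssociateCohort:
    @staticmethod
    def _variant(pos, gene="JAK2"):
        return AnnotatedVariant(
            chrom="9", pos=pos, ref="G", alt="A", gene=gene,
            func_class=FuncClass.NONSYNONYMOUS_SNV, cadd_phred=25.0,
        )

    def test_reference_counts_reproduce_or_and_p(self):
        v = self._variant(5073770)
        case = {v.key: CohortAlleleCounts(9, 238, "discovery")}
        ctrl = {v.key: CohortAlleleCounts(20, 2674, "local")}
        (r,) = associate_cohort([v], case, ctrl, "local")
        assert round(r.or_estimate, 1) == 5.2
        assert r.p_raw == pytest.approx(0.000327, rel=5e-3)
        assert r.p_fdr == r.p_raw  # single-variant family

    def test_untestable_variant_excluded_with_warning(self):
        v1, v2 = self._variant(100), self._variant(200)
        case = {v.key: CohortAlleleCounts(2, 238) for v in (v1, v2)}
        ctrl = {v1.key: CohortAlleleCounts(0, 2674)}
        with pytest.warns(UserWarning):
            results = associate_cohort([v1, v2], case, ctrl, "local")
        assert [r.variant_key for r in results] == [v1.key]

    def test_fdr_never_below_raw_p(self, rng):
        variants = [self._variant(int(pos)) for pos in range(100, 130)]
        case = {v.key: CohortAlleleCounts(int(rng.integers(0, 5)), 238) for v in variants}
        ctrl = {v.key: CohortAlleleCounts(int(rng.integers(0, 12)), 2674) for v in variants}
        results = associate_cohort(variants, case, ctrl, "local", compute_ci=False)
        assert all(r.p_fdr >= r.p_raw - 1e-15 for r in results)
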
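"""Carrier counting, one-tailed Fisher test, complement test, and power."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from homburden import (
    CarrierCounts,
    GeneSet,
    burden_test,
    classify_variants,
    complement_burden,
    count_hom_carriers,
    fisher_one_tailed,
    fisher_power,
    run_qc,
)

from conftest import build_matrix


def hypergeom_tail_oracle(a, n1, b, n2):
    """Brute-force one-tailed p: enumerate the hypergeometric support.

    Conditional on margins (n1 cases, n2 controls, K = a + b carriers),
    sum the point probabilities of every table with at least `a` case
    carriers.
    """
    n = n1 + n2
    k = a + b
    denom = math.comb(n, k)
    p = 0
    for x in range(a, min(k, n1) + 1):
        if k - x <= n2:
            p += math.comb(n1, x) * math.comb(n2, k - x)
    return p / denom


class TestFisherOneTailed:
    @pytest.mark.parametrize(
        "case_hom,expected",
        [(6, 0.0055), (5, 0.0131), (4, 0.0311), (3, 0.0741)],
    )
    def test_published_category_pvalues(self, case_hom, expected):
        p = fisher_one_tailed(CarrierCounts(case_hom, 4225, 0, 5834))
        assert p == pytest.approx(expected, abs=1e-4)

    def test_zero_control_closed_form(self):
        """With no control carriers the p equals ∏ (n1−i)/(N−i)."""
        for a in (1, 3, 6, 10):
            p = fisher_one_tailed(CarrierCounts(a, 4225, 0, 5834))
            closed = math.prod((4225 - i) / (10059 - i) for i in range(a))
            assert p == pytest.approx(closed, rel=1e-10)

    def test_no_carriers_gives_one(self):
        assert fisher_one_tailed(CarrierCounts(0, 50, 0, 60)) == 1.0

    def test_small_table_full_enumeration(self):
        # 2/5 vs 0/5 carriers: 56/252
        p = fisher_one_tailed(CarrierCounts(2, 5, 0, 5))
        assert p == pytest.approx(56 / 252, rel=1e-12)

    @given(
        n1=st.integers(1, 100),
        n2=st.integers(1, 100),
        a=st.integers(0, 100),
        b=st.integers(0, 100),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_enumeration_oracle(self, n1, n2, a, b):
        a = min(a, n1)
        b = min(b, n2)
        p = fisher_one_tailed(CarrierCounts(a, n1, b, n2))
        assert p == pytest.approx(hypergeom_tail_oracle(a, n1, b, n2), rel=1e-9)

    def test_monotone_in_case_count(self):
        ps = [
            fisher_one_tailed(CarrierCounts(a, 200, 3, 300)) for a in range(0, 30)
        ]
        assert all(x >= y for x, y in zip(ps, ps[1:]))

    def test_degenerate_margins_error(self):
        with pytest.raises(ValueError):
            fisher_one_tailed(CarrierCounts(0, 0, 0, 10))


class TestCounting:
    def make_classified(self, matrix):
        return classify_variants(matrix, dataset_maf_threshold=0.5)

    def test_subject_counted_once(self):
        # one case homozygous at two qualifying variants of the set
        geno = np.zeros((2, 6), dtype=np.int8)
        geno[0, 0] = 2
        geno[1, 0] = 2
        m = build_matrix(geno, [1, 1, 1, 0, 0, 0], gene=["GA", "GB"])
        cls = self.make_classified(m)
        counts = count_hom_carriers(m, cls, GeneSet("s", ["GA", "GB"]), "A")
        assert counts == CarrierCounts(1, 3, 0, 3)

    def test_het_is_not_a_carrier(self):
        geno = np.zeros((1, 4), dtype=np.int8)
        geno[0, :] = 1
        m = build_matrix(geno, [1, 1, 0, 0], gene=["GA"])
        cls = self.make_classified(m)
        counts = count_hom_carriers(m, cls, GeneSet("s", ["GA"]), "A")
        assert counts.case_hom == 0 and counts.control_hom == 0

    def test_empty_qualification_returns_zero_counts(self):
        geno = np.zeros((1, 4), dtype=np.int8)
        geno[0, 0] = 2
        # common in population panels → excluded from category B
        m = build_matrix(geno, [1, 1, 0, 0], gene=["GA"], popmax_af=[0.4])
        cls = classify_variants(m, dataset_maf_threshold=0.5)
        counts = count_hom_carriers(m, cls, GeneSet("s", ["GA"]), "B")
        assert counts == CarrierCounts(0, 2, 0, 2)

    def test_disjoint_gene_set_warns(self):
        geno = np.zeros((1, 4), dtype=np.int8)
        m = build_matrix(geno, [1, 1, 0, 0], gene=["GA"])
        cls = self.make_classified(m)
        with pytest.warns(UserWarning):
            counts = count_hom_carriers(m, cls, GeneSet("s", ["NOPE"]), "A")
        assert counts.case_hom == 0

    def test_counts_monotone_across_categories(self, small_cohort):
        matrix, truth = small_cohort
        clean = run_qc(matrix)
        cls = classify_variants(clean, dataset_maf_threshold=0.05)
        gs = GeneSet("t", truth.target_genes)
        counts = [count_hom_carriers(clean, cls, gs, c) for c in "ABCD"]
        homs = [c.case_hom + c.control_hom for c in counts]
        assert homs == sorted(homs, reverse=True)

    def test_planted_carriers_recovered(self, planted_cohort):
        matrix, truth = planted_cohort
        clean = run_qc(matrix)
        cls = classify_variants(clean, dataset_maf_threshold=0.05)
        gs = GeneSet("t", truth.target_genes)
        counts = count_hom_carriers(clean, cls, gs, "A")
        # plants are clean calls, so they all survive QC
        assert counts.case_hom >= len(truth.planted_case_carriers)


class TestComplement:
    def test_excluding_all_genes_gives_p_one(self, small_cohort):
        matrix, _ = small_cohort
        clean = run_qc(matrix)
        cls = classify_variants(clean, dataset_maf_threshold=0.05)
        every = GeneSet("all", set(clean.variants["gene"]))
        res = complement_burden(clean, cls, every, "A")
        assert res.counts.case_hom == 0 and res.counts.control_hom == 0
        assert res.fisher_p == 1.0

    def test_empty_exclusion_equals_whole_genome(self, small_cohort):
        matrix, _ = small_cohort
        clean = run_qc(matrix)
        cls = classify_variants(clean, dataset_maf_threshold=0.05)
        whole = burden_test(
            clean, cls, GeneSet("all", set(clean.variants["gene"])), "A"
        )
        comp = complement_burden(clean, cls, GeneSet("none", ["ZZZ_ABSENT"]), "A")
        assert comp.counts == whole.counts

    def test_enrichment_is_target_specific(self, planted_cohort):
        """Planted signal shows in the target set, not its complement."""
        matrix, truth = planted_cohort
        clean = run_qc(matrix)
        # ultra-rare regime (the screen's): plants qualify, background is thin
        cls = classify_variants(clean, dataset_maf_threshold=0.005)
        gs = GeneSet("t", truth.target_genes)
        target = burden_test(clean, cls, gs, "A")
        comp = complement_burden(clean, cls, gs, "A")
        assert target.fisher_p < comp.fisher_p


class TestPower:
    def test_published_underpowered_scenario(self):
        """Case frequency 3/4225 vs 0: rejection needs ≥4 case carriers,
        giving power ≈ 0.35 at α = 0.05."""
        power = fisher_power(3 / 4225, 0.0, 4225, 5834)
        from scipy import stats

        assert power == pytest.approx(stats.binom.sf(3, 4225, 3 / 4225), rel=1e-9)
        assert 0.33 <= round(power, 2) <= 0.35

    def test_no_effect_gives_zero_power(self):
        assert fisher_power(0.0, 0.0, 100, 100) == 0.0

    def test_full_effect_gives_power_near_one(self):
        assert fisher_power(1.0, 0.0, 500, 500) > 0.999

    def test_alpha_validated(self):
        with pytest.raises(ValueError):
            fisher_power(0.1, 0.0, 50, 50, alpha=1.5)

    def test_exact_and_montecarlo_agree(self):
        exact = fisher_power(0.02, 0.005, 400, 500)
        mc = fisher_power(
            0.02, 0.005, 400, 500, method="montecarlo", n_reps=100_000, seed=5
        )
        se = math.sqrt(exact * (1 - exact) / 100_000)
        assert abs(mc - exact) < 4 * se
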
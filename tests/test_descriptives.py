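import math

import numpy as np
import pytest
from scipy import stats

from hapstar.descriptives import (
    ContingencyTable2x2,
    association_test,
    fisher_exact,
    odds_ratio,
    pearson_chi_square,
    prevalence_ratio,
    table1_report,
    welch_t_test,
)


def r2(x):
    return round(x, 2)


class TestPrevalenceRatio:
    @pytest.mark.parametrize("a,b,c,d,pr,lo,hi", [
        # stillbirth vs alive across fuel columns
        (17_598, 100_669, 503, 7_626, 2.40, 2.21, 2.62),
        # preterm vs term
        (345, 35_972, 59, 2_856, 0.47, 0.36, 0.62),
        # low vs normal birth weight
        (442, 5_373, 113, 1_633, 1.17, 0.96, 1.43),
        # smoker vs non-smoker
        (75, 36_771, 18, 4_392, 0.50, 0.30, 0.83),
    ])
    def test_published_rows_to_two_decimals(self, a, b, c, d, pr, lo, hi):
        est = prevalence_ratio(ContingencyTable2x2(a, b, c, d))
        assert (r2(est.estimate), r2(est.ci_low), r2(est.ci_high)) == \
            (pr, lo, hi)

    def test_balanced_table_is_unity_with_straddling_ci(self):
        est = prevalence_ratio(ContingencyTable2x2(10, 90, 10, 90))
        assert est.estimate == pytest.approx(1.0)
        assert est.ci_low < 1.0 < est.ci_high

    def test_zero_numerator_is_an_error(self):
        with pytest.raises(ValueError, match="undefined PR"):
            prevalence_ratio(ContingencyTable2x2(0, 10, 5, 5))

    def test_exposure_swap_inverts(self):
        t = ContingencyTable2x2(30, 70, 10, 90)
        est = prevalence_ratio(t)
        inv = prevalence_ratio(t.swap_exposure())
        assert inv.estimate == pytest.approx(1 / est.estimate)
        assert inv.ci_low == pytest.approx(1 / est.ci_high)
        assert inv.ci_high == pytest.approx(1 / est.ci_low)


class TestOddsRatio:
    @pytest.mark.parametrize("a,b,c,d,orr", [
        (6_062, 252, 14_173, 115, 0.20),    # primary vs no education
        (14_219, 2_189, 14_173, 115, 0.05),  # secondary vs no education
        (2_392, 1_854, 14_173, 115, 0.01),   # higher vs no education
        (7_453, 86, 3_431, 2_124, 53.65),    # North-East vs South-West
    ])
    def test_published_rows(self, a, b, c, d, orr):
        est = odds_ratio(ContingencyTable2x2(a, b, c, d))
        assert r2(est.estimate) == orr

    def test_identical_odds_give_unity(self):
        est = odds_ratio(ContingencyTable2x2(20, 10, 40, 20))
        assert est.estimate == pytest.approx(1.0)

    def test_zero_cell_is_an_error(self):
        with pytest.raises(ValueError):
            odds_ratio(ContingencyTable2x2(5, 0, 10, 10))

    def test_matches_statsmodels_woolf_interval(self):
        sm_ct = pytest.importorskip("statsmodels.stats.contingency_tables")
        t = ContingencyTable2x2(30, 70, 15, 85)
        est = odds_ratio(t)
        ref = sm_ct.Table2x2(np.array([[30, 70], [15, 85]]))
        lo, hi = ref.oddsratio_confint()
        assert est.estimate == pytest.approx(ref.oddsratio)
        assert (est.ci_low, est.ci_high) == pytest.approx((lo, hi))

    def test_rare_outcome_odds_ratio_near_prevalence_ratio(self, rng):
        """Rare-disease consistency: with prevalence < 2% in both arms the
        OR approximates the PR to within 5%."""
        for _ in range(50):
            n1, n0 = 20_000, 20_000
            p1, p0 = rng.uniform(0.002, 0.02, size=2)
            a, c = rng.binomial(n1, p1), rng.binomial(n0, p0)
            if a == 0 or c == 0:
                continue
            t = ContingencyTable2x2(a, n1 - a, c, n0 - c)
            pr = prevalence_ratio(t).estimate
            orr = odds_ratio(t).estimate
            assert abs(orr - pr) / pr < 0.05


class TestChiSquare:
    def test_proportional_table_zero_statistic(self):
        res = pearson_chi_square([[10, 20], [30, 60]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert res.df == 1

    def test_matches_direct_formula(self):
        # chi2 = N (ad - bc)^2 / (r1 r2 c1 c2), computed by hand
        a, b, c, d = 10, 20, 20, 10
        expected = 60 * (a * d - b * c) ** 2 / (30 * 30 * 30 * 30)
        res = pearson_chi_square([[a, b], [c, d]])
        assert res.statistic == pytest.approx(expected)
        assert res.p_value == pytest.approx(stats.chi2.sf(expected, 1))

    def test_stillbirth_fuel_association_is_extreme(self):
        res = pearson_chi_square([[17_598, 503], [100_669, 7_626]])
        assert res.p_value < 1e-4

    def test_invariant_to_permutation(self, rng):
        t = rng.integers(5, 50, size=(3, 4))
        base = pearson_chi_square(t).statistic
        perm = t[[2, 0, 1]][:, [3, 1, 0, 2]]
        assert pearson_chi_square(perm).statistic == pytest.approx(base)

    def test_degenerate_margin_rejected(self):
        with pytest.raises(ValueError):
            pearson_chi_square([[0, 0], [5, 5]])


def _fisher_enumeration(a, b, c, d):
    """Brute-force two-sided Fisher p: sum hypergeometric probabilities of
    all tables with the observed margins that are no more probable."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(k):
        return (math.comb(r1, k) * math.comb(r2, c1 - k)
                / math.comb(n, c1))

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = prob(a)
    return sum(prob(k) for k in range(lo, hi + 1)
               if prob(k) <= p_obs * (1 + 1e-9))


class TestFisherExact:
    @pytest.mark.parametrize("table", [
        (1, 9, 9, 1), (0, 10, 10, 0), (3, 7, 5, 5), (2, 8, 1, 12),
    ])
    def test_matches_enumeration_oracle(self, table):
        p = fisher_exact(ContingencyTable2x2(*table)).p_value
        assert p == pytest.approx(_fisher_enumeration(*table), rel=1e-9)

    def test_balanced_table_p_is_one(self):
        assert fisher_exact(ContingencyTable2x2(5, 5, 5, 5)).p_value == \
            pytest.approx(1.0)

    def test_switch_rule_uses_fisher_for_sparse_tables(self):
        res = association_test([[1, 2], [3, 4]])
        assert res.method == "fisher_exact"
        res = association_test([[100, 200], [300, 400]])
        assert res.method == "pearson_chi_square"


class TestWelch:
    def test_identical_samples(self):
        res = welch_t_test([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_closed_form(self):
        # x=(1,2,3), y=(4,5,6): t = -3 / sqrt(2/3), Satterthwaite df = 4
        res = welch_t_test([1, 2, 3], [4, 5, 6])
        t_hand = -3 / math.sqrt(2 / 3)
        assert res.statistic == pytest.approx(t_hand)
        assert res.df == pytest.approx(4.0)
        assert res.p_value == pytest.approx(2 * stats.t.sf(abs(t_hand), 4))

    def test_location_invariance(self, rng):
        x, y = rng.normal(size=20), rng.normal(1, 1, size=25)
        a = welch_t_test(x, y)
        b = welch_t_test(x + 100, y + 100)
        assert a.statistic == pytest.approx(b.statistic)

    def test_zero_variance_both_samples_rejected(self):
        with pytest.raises(ValueError):
            welch_t_test([1, 1, 1], [2, 2, 2])


class TestTable1Report:
    def test_report_structure_and_estimator_kinds(self, small_cohort,
                                                  tmp_path):
        out = tmp_path / "table1.csv"
        df = table1_report(small_cohort.births, out)
        assert out.exists()
        assert list(df.columns) == [
            "characteristic", "level", "n_overall", "n_clean", "n_unclean",
            "estimate", "ci_low", "ci_high", "estimator_kind", "p_value"]
        kinds = df.set_index("characteristic")["estimator_kind"]
        assert set(kinds.loc[["birth_status", "smoking"]]) == \
            {"prevalence_ratio"}
        assert set(kinds.loc[["education", "wealth"]]) == {"odds_ratio"}
        # one reference row per categorical characteristic
        refs = df[df["level"].str.endswith("(ref)")]
        assert set(refs["characteristic"]) == {"education", "wealth",
                                               "region"}

    def test_reference_level_is_configurable(self, small_cohort):
        df = table1_report(small_cohort.births,
                           reference={"education": "secondary"})
        ref_row = df[(df.characteristic == "education")
                     & df.level.str.endswith("(ref)")]
        assert ref_row["level"].iloc[0] == "secondary (ref)"
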
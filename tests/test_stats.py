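"""HWE, indicator-OLS contrasts, Spearman/AS 89, and contingency chi-square."""

from itertools import permutations

import numpy as np
import pytest
import scipy.stats as sps
from hypothesis import given, settings
from hypothesis import strategies as st

from tamoxmr.stats import (
    BonferroniPlan,
    SpearmanMethod,
    contingency_chisq,
    encode_categories,
    hwe_chisq,
    indicator_ols,
    spearman_as89,
)


class TestHWE:
    def test_exact_proportions_give_zero_statistic(self):
        res = hwe_chisq((25, 50, 25))
        assert res.chi2 == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_departure(self):
        # p = q = 0.5 -> expected (25, 50, 25); chi2 = 1 + 2 + 1 = 4
        res = hwe_chisq((30, 40, 30))
        assert res.chi2 == pytest.approx(4.0)
        assert res.p_value == pytest.approx(0.0455, abs=2e-4)

    def test_no_heterozygotes_is_an_extreme_departure(self):
        res = hwe_chisq((100, 0, 100))
        assert res.p_value < 1e-3
        assert res.chi2 == pytest.approx(200.0)

    def test_monomorphic_variant_is_in_equilibrium_by_convention(self):
        res = hwe_chisq((50, 0, 0))
        assert res.chi2 == 0.0 and res.p_value == 1.0

    @settings(max_examples=100, derandomize=True)
    @given(
        counts=st.tuples(
            st.integers(0, 500), st.integers(0, 500), st.integers(0, 500)
        ).filter(lambda c: sum(c) > 0)
    )
    def test_invariant_under_allele_label_swap(self, counts):
        a = hwe_chisq(counts)
        b = hwe_chisq(counts[::-1])
        assert a.chi2 == pytest.approx(b.chi2, rel=1e-12, abs=1e-12)


class TestIndicatorOLS:
    def test_identical_groups_give_zero_coefficients(self):
        values = [5.0, 5.0, 5.0, 5.0, 5.1, 4.9]
        cats = ["EM/EM", "EM/EM", "PM/PM", "PM/PM", "EM/PM", "EM/PM"]
        res = indicator_ols(values, cats)
        c = res.contrasts.set_index("group")
        assert c.loc["PM/PM", "coefficient"] == pytest.approx(0.0, abs=1e-12)
        assert not c["significant"].any()

    def test_toy_group_mean_difference(self):
        values = [7.0, 8.0, 9.0, 1.0, 2.0, 3.0]
        cats = ["EM/EM"] * 3 + ["PM/PM"] * 3
        res = indicator_ols(values, cats)
        assert res.reference_mean == pytest.approx(8.0)
        assert res.contrasts.set_index("group").loc["PM/PM", "coefficient"] \
            == pytest.approx(-6.0)

    @settings(max_examples=50, derandomize=True)
    @given(data=st.data())
    def test_coefficients_equal_group_mean_differences(self, data):
        cats_pool = ["EM/EM", "EM/PM", "PM/PM", "EM/IM"]
        n = data.draw(st.integers(8, 40))
        cats = data.draw(
            st.lists(st.sampled_from(cats_pool), min_size=n, max_size=n).filter(
                lambda c: "EM/EM" in c and len(set(c)) >= 2
            )
        )
        values = data.draw(
            st.lists(
                st.floats(-100, 100, allow_nan=False),
                min_size=n, max_size=n,
            ).filter(lambda v: len(set(v)) > 1)
        )
        values = np.asarray(values)
        try:
            res = indicator_ols(values, cats)
        except ValueError:
            return  # zero residual variance draw
        ref_mean = values[np.array(cats) == "EM/EM"].mean()
        for _, row in res.contrasts.iterrows():
            grp_mean = values[np.array(cats) == row["group"]].mean()
            assert row["coefficient"] == pytest.approx(
                grp_mean - ref_mean, rel=1e-8, abs=1e-8
            )

    def test_singleton_group_is_retained(self):
        values = [7.0, 8.0, 9.0, 2.0]
        cats = ["EM/EM"] * 3 + ["PM/PM"]
        res = indicator_ols(values, cats)
        c = res.contrasts.set_index("group")
        assert c.loc["PM/PM", "n"] == 1
        assert c.loc["PM/PM", "coefficient"] == pytest.approx(-6.0)

    def test_constant_outcome_raises(self):
        with pytest.raises(ValueError, match="residual variance"):
            indicator_ols([1.0, 1.0, 1.0, 1.0], ["EM/EM", "EM/EM", "PM/PM", "PM/PM"])

    def test_empty_reference_group_raises(self):
        with pytest.raises(ValueError, match="reference"):
            indicator_ols([1.0, 2.0], ["PM/PM", "EM/PM"])


class TestBonferroniPlan:
    def test_threshold_is_alpha_over_the_full_family(self):
        plan = BonferroniPlan()
        assert plan.threshold == pytest.approx(0.05 / 72)
        assert plan.threshold == pytest.approx(6.9e-4, rel=0.01)


def _brute_force_two_sided(x, y):
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    q = np.sum((rx - ry) ** 2)
    stats = [
        np.sum((rx - ry[list(p)]) ** 2) for p in permutations(range(len(x)))
    ]
    stats = np.asarray(stats)
    lo = np.mean(stats <= q)
    hi = np.mean(stats >= q)
    return min(1.0, 2 * min(lo, hi))


class TestSpearmanAS89:
    def test_perfect_monotone_pair(self):
        res = spearman_as89([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert res.r == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_exact_small_sample_matches_independent_enumeration(self):
        x, y = [1, 2, 3, 4, 5], [2, 1, 4, 3, 5]
        res = spearman_as89(x, y)
        assert res.method is SpearmanMethod.EXACT
        assert res.r == pytest.approx(0.8)
        assert res.p_value == pytest.approx(_brute_force_two_sided(x, y))
        # frozen from R cor.test(..., method="spearman", exact=TRUE)
        assert res.p_value == pytest.approx(0.1333333333, rel=1e-8)

    @pytest.mark.parametrize(
        "y,expected_r,expected_p",
        [
            ([3, 1, 2, 5, 4, 7, 6], 0.8214286, 0.03412698413),
            ([7, 5, 6, 3, 4, 1, 2], -0.8928571, 0.0123015873),
        ],
    )
    def test_exact_n7_matches_frozen_r_values(self, y, expected_r, expected_p):
        res = spearman_as89(list(range(1, 8)), y)
        assert res.method is SpearmanMethod.EXACT
        assert res.r == pytest.approx(expected_r, rel=1e-6)
        assert res.p_value == pytest.approx(expected_p, rel=1e-8)

    def test_exact_mode_equals_permutation_oracle_for_all_small_n(self, rng):
        for n in (4, 5, 6, 7):
            for _ in range(5):
                x = rng.permutation(n) + 1
                y = rng.permutation(n) + 1
                res = spearman_as89(x, y)
                assert res.method is SpearmanMethod.EXACT
                assert res.p_value == pytest.approx(
                    _brute_force_two_sided(x, y), abs=1e-12
                )

    def test_edgeworth_matches_frozen_r_values(self):
        # frozen from R cor.test (AS 89 path, 9 < n < 1290, no ties)
        x20 = [16, 10, 15, 8, 13, 11, 7, 20, 4, 1, 17, 6, 12, 19, 3, 5, 18, 2, 14, 9]
        y20 = [19, 9, 10, 8, 5, 2, 7, 12, 6, 16, 1, 13, 20, 3, 15, 17, 11, 4, 14, 18]
        res = spearman_as89(x20, y20)
        assert res.method is SpearmanMethod.AS89_APPROX
        assert res.r == pytest.approx(-0.1428571, rel=1e-6)
        assert res.p_value == pytest.approx(0.546534964824, rel=1e-6)

    def test_edgeworth_matches_frozen_r_values_n60(self):
        x60 = [59, 22, 56, 19, 34, 47, 50, 28, 53, 40, 3, 26, 25, 52, 7, 9, 51,
               16, 5, 10, 14, 38, 29, 49, 8, 57, 43, 27, 31, 36, 39, 1, 23, 46,
               11, 30, 54, 45, 18, 13, 41, 60, 6, 32, 2, 48, 42, 55, 4, 12, 15,
               21, 20, 44, 35, 33, 58, 24, 37, 17]
        y60 = [33, 7, 8, 44, 60, 52, 48, 31, 9, 16, 34, 4, 42, 26, 32, 47, 5,
               38, 41, 17, 39, 51, 3, 21, 46, 56, 12, 18, 37, 35, 25, 55, 58,
               53, 27, 1, 11, 28, 19, 59, 43, 54, 20, 14, 24, 29, 36, 6, 22,
               49, 10, 30, 50, 2, 13, 23, 40, 15, 57, 45]
        res = spearman_as89(x60, y60)
        assert res.p_value == pytest.approx(0.341962590255, rel=1e-6)

    def test_ties_use_midranks_and_the_approximation(self):
        x = [0, 0, 1, 1, 2, 2, 3, 3, 4, 4, 5, 5]
        y = [1.0, 2.0, 1.5, 3.0, 2.5, 4.0, 3.5, 5.0, 4.5, 6.0, 5.5, 7.0]
        res = spearman_as89(x, y)
        assert res.method is SpearmanMethod.AS89_APPROX
        expected_r = sps.spearmanr(x, y).statistic  # independent r cross-check
        assert res.r == pytest.approx(expected_r, rel=1e-12)

    def test_strong_association_yields_a_tiny_but_valid_p(self, rng):
        x = np.arange(200.0)
        y = x + rng.normal(0, 10, 200)
        res = spearman_as89(x, y)
        assert 0 < res.p_value < 1e-20

    def test_constant_vector_is_an_error(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_as89([1, 1, 1, 1], [1, 2, 3, 4])


class TestContingency:
    def test_independent_table_gives_zero(self):
        res = contingency_chisq([[50, 50], [50, 50]])
        assert res.chi2 == pytest.approx(0.0)

    def test_hand_formula_2x2(self):
        # chi2 = n (ad - bc)^2 / (row1 row2 col1 col2) = 200*(8100-100)^2/1e8
        res = contingency_chisq([[90, 10], [10, 90]])
        assert res.chi2 == pytest.approx(128.0)
        assert res.p_value < 1e-3
        assert res.df == 1

    def test_low_expected_cell_sets_warning_flag(self):
        res = contingency_chisq([[1, 200], [0, 200]])
        assert res.low_expected_warning

    def test_2xk_degrees_of_freedom(self):
        res = contingency_chisq([[10, 20, 30], [30, 20, 10]])
        assert res.df == 2


class TestEncodings:
    def test_category_rank_follows_the_fixed_order(self):
        cats = ["PM/PM", "IM/PM", "IM/IM", "EM/PM", "EM/IM", "EM/EM", "EM/UM"]
        assert list(encode_categories(cats)) == [0, 1, 2, 3, 4, 5, 6]

    def test_functional_allele_count_alternative(self):
        enc = encode_categories(
            ["PM/PM", "IM/IM", "EM/PM", "EM/EM", "EM/UM"],
            encoding="functional_allele_count",
        )
        assert list(enc) == [0.0, 1.0, 1.0, 2.0, 3.0]
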
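import math

import numpy as np
import pytest
from scipy import stats

from dentalage import (
    bias_regression,
    classify_p,
    compare_from_summary,
    compare_group,
)
from dentalage.accuracy import (
    HIGHLY_SIGNIFICANT,
    NON_SIGNIFICANT,
    SIGNIFICANT,
    VERY_HIGHLY_SIGNIFICANT,
    descriptive_group,
)
from dentalage.errors import DegenerateDataError, InsufficientDataError

# Published per-stratum summary rows for an Egyptian cohort of 160 children:
# (label, sex, n, ca_mean, ca_sd, eda_mean, eda_sd, printed mean_diff,
#  arithmetically consistent with the printed means at printed precision?)
# Two male rows carry a printed difference that cannot be reproduced from the
# printed means (off by 0.08) — a data-entry inconsistency in the source
# table, kept here as printed and flagged inconsistent.
STRATUM_ROWS = [
    ("3 to <4", "M", 10, 3.21, 0.35, 4.40, 1.04, 1.19, True),
    ("3 to <4", "F", 8, 3.67, 0.30, 4.55, 0.79, 0.87, True),
    ("4 to <5", "M", 10, 4.39, 0.39, 4.64, 0.81, 0.25, True),
    ("4 to <5", "F", 9, 4.08, 0.16, 4.68, 0.78, 0.60, True),
    ("5 to <6", "M", 11, 5.08, 0.27, 5.99, 0.66, 0.90, True),
    ("5 to <6", "F", 15, 5.32, 0.29, 5.92, 0.83, 0.60, True),
    ("6 to <7", "M", 5, 6.00, 0.00, 6.10, 1.10, 0.18, False),
    ("6 to <7", "F", 10, 6.42, 0.27, 6.86, 0.45, 0.44, True),
    ("7 to <8", "M", 10, 7.28, 0.32, 7.86, 0.27, 0.58, True),
    ("7 to <8", "F", 10, 7.34, 0.31, 7.57, 0.30, 0.23, True),
    ("8 to <9", "M", 10, 8.35, 0.28, 8.60, 0.38, 0.25, True),
    ("8 to <9", "F", 10, 8.28, 0.33, 8.36, 0.52, 0.08, True),
    ("9 to <10", "M", 8, 9.00, 0.00, 8.40, 0.39, -0.60, True),
    ("9 to <10", "F", 12, 9.20, 0.23, 9.14, 0.47, -0.06, True),
    ("10 to <11", "M", 10, 10.21, 0.25, 10.70, 0.35, 0.57, False),
    ("10 to <11", "F", 12, 10.42, 0.32, 10.41, 0.50, -0.008, True),
]


class TestClassifyP:
    @pytest.mark.parametrize(
        "p, expected",
        [
            (0.05, NON_SIGNIFICANT),  # boundary is inclusive on the ns side
            (1.0, NON_SIGNIFICANT),
            (0.049, SIGNIFICANT),
            (0.005, HIGHLY_SIGNIFICANT),
            (0.0005, VERY_HIGHLY_SIGNIFICANT),
            (0.0, VERY_HIGHLY_SIGNIFICANT),
        ],
    )
    def test_category_boundaries(self, p, expected):
        assert classify_p(p) == expected

    def test_out_of_domain_rejected(self):
        with pytest.raises(ValueError):
            classify_p(1.5)

    def test_monotone_smaller_p_never_weaker(self):
        order = [NON_SIGNIFICANT, SIGNIFICANT, HIGHLY_SIGNIFICANT, VERY_HIGHLY_SIGNIFICANT]
        grid = np.linspace(0, 1, 400)
        ranks = [order.index(classify_p(p)) for p in grid]
        assert all(a >= b for a, b in zip(ranks, ranks[1:]))


class TestCompareFromSummary:
    def test_seven_to_eight_year_male_stratum(self):
        diff, t, p, _ = compare_from_summary(7.28, 0.32, 10, 7.86, 0.27, 10)
        assert diff == pytest.approx(0.58)
        # hand-pooled: s_p^2 = 0.08765, se = 0.13240, t = 0.58/0.13240
        assert t == pytest.approx(0.58 / math.sqrt(0.08765 * 0.2), abs=1e-6)
        assert t == pytest.approx(4.381, abs=1e-3)
        assert p < 0.001

    def test_matches_scipy_summary_t(self):
        diff, t, p, _ = compare_from_summary(5.1, 0.4, 12, 5.9, 0.7, 9)
        ref = stats.ttest_ind_from_stats(5.9, 0.7, 9, 5.1, 0.4, 12, equal_var=True)
        assert t == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_welch_matches_scipy(self):
        _, t, p, _ = compare_from_summary(5.1, 0.4, 12, 5.9, 0.7, 9, welch=True)
        ref = stats.ttest_ind_from_stats(5.9, 0.7, 9, 5.1, 0.4, 12, equal_var=False)
        assert t == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_equal_means_equal_sds(self):
        diff, t, p, _ = compare_from_summary(5.0, 0.3, 10, 5.0, 0.3, 10)
        assert (diff, t) == (0.0, 0.0) and p == 1.0

    def test_degenerate_conventions(self):
        assert compare_from_summary(5.0, 0.0, 10, 5.0, 0.0, 10) == (0.0, 0.0, 1.0, True)
        diff, t, p, flag = compare_from_summary(5.0, 0.0, 10, 6.0, 0.0, 10)
        assert diff == 1.0 and math.isinf(t) and p == 0.0 and flag

    def test_swap_negates_t_and_diff_preserves_p(self):
        d1, t1, p1, _ = compare_from_summary(4.0, 0.5, 8, 5.0, 0.6, 11)
        d2, t2, p2, _ = compare_from_summary(5.0, 0.6, 11, 4.0, 0.5, 8)
        assert d2 == pytest.approx(-d1) and t2 == pytest.approx(-t1)
        assert p2 == pytest.approx(p1, abs=1e-15)

    def test_small_samples_rejected(self):
        with pytest.raises(InsufficientDataError):
            compare_from_summary(5.0, 0.3, 1, 5.0, 0.3, 10)

    @pytest.mark.parametrize(
        "label, sex, n, ca_m, ca_sd, eda_m, eda_sd, printed_diff, consistent", STRATUM_ROWS
    )
    def test_stratum_arithmetic_identity(
        self, label, sex, n, ca_m, ca_sd, eda_m, eda_sd, printed_diff, consistent
    ):
        """Printed mean difference equals printed EDA mean - CA mean (where the
        source row is internally consistent at its printed precision)."""
        diff, _, _, _ = compare_from_summary(ca_m, ca_sd, n, eda_m, eda_sd, n)
        if consistent:
            assert diff == pytest.approx(printed_diff, abs=0.011)
        else:
            assert abs(diff - printed_diff) == pytest.approx(0.08, abs=0.011)


class TestCompareGroup:
    def test_identical_columns(self):
        s = compare_group([3.0, 4.0, 5.0], [3.0, 4.0, 5.0])
        assert s.mean_diff == 0.0 and s.t_stat == 0.0 and s.p_value == 1.0
        assert s.category == NON_SIGNIFICANT

    def test_constant_ca_with_varying_eda_is_finite(self):
        s = compare_group([6.0] * 5, [6.3, 5.9, 7.1, 6.4, 6.0])
        assert math.isfinite(s.t_stat) and 0.0 <= s.p_value <= 1.0

    def test_consistent_with_summary_route(self):
        rng = np.random.default_rng(11)
        ca = rng.normal(7.0, 0.3, 14)
        eda = rng.normal(7.5, 0.4, 14)
        s = compare_group(ca, eda)
        diff, t, p, _ = compare_from_summary(
            s.ca_mean, s.ca_sd, s.n, s.eda_mean, s.eda_sd, s.n
        )
        assert s.t_stat == pytest.approx(t, abs=1e-12)
        assert s.p_value == pytest.approx(p, abs=1e-12)

    def test_matches_scipy_on_raw_data(self):
        rng = np.random.default_rng(5)
        ca = rng.normal(8.0, 0.3, 10)
        eda = rng.normal(8.4, 0.5, 10)
        s = compare_group(ca, eda)
        ref = stats.ttest_ind(eda, ca, equal_var=True)
        assert s.t_stat == pytest.approx(ref.statistic, abs=1e-10)
        assert s.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_paired_variant_matches_scipy(self):
        rng = np.random.default_rng(6)
        ca = rng.normal(8.0, 0.3, 10)
        eda = ca + rng.normal(0.3, 0.2, 10)
        s = compare_group(ca, eda, paired=True)
        ref = stats.ttest_rel(eda, ca)
        assert s.t_stat == pytest.approx(ref.statistic, abs=1e-10)
        assert s.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_single_child_is_descriptive_only(self):
        with pytest.raises(InsufficientDataError):
            compare_group([6.5], [6.8])
        s = descriptive_group([6.5], [6.8])
        assert s.n == 1 and s.t_stat is None and s.p_value is None
        assert s.mean_diff == pytest.approx(0.3)


class TestBiasRegression:
    def test_constant_difference(self):
        fit = bias_regression([3.0, 5.0, 7.0, 9.0], [0.4, 0.4, 0.4, 0.4])
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.4)
        assert fit.overall_mean_diff == pytest.approx(0.4)

    def test_exact_linear_recovery(self):
        ca = np.array([3.0, 4.5, 6.0, 8.0, 10.5])
        d = -0.12 * ca + 0.9
        fit = bias_regression(ca, d)
        assert fit.slope == pytest.approx(-0.12, abs=1e-12)
        assert fit.intercept == pytest.approx(0.9, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(42)
        ca = rng.uniform(3, 11, 60)
        d = 0.05 * ca + rng.normal(0.4, 0.3, 60)
        fit = bias_regression(ca, d)
        # brute-force normal equations
        A = np.array([[len(ca), ca.sum()], [ca.sum(), (ca**2).sum()]])
        b = np.array([d.sum(), (ca * d).sum()])
        intercept, slope = np.linalg.solve(A, b)
        assert fit.slope == pytest.approx(slope, abs=1e-10)
        assert fit.intercept == pytest.approx(intercept, abs=1e-10)
        assert fit.overall_sd == pytest.approx(np.std(d, ddof=1), abs=1e-12)

    def test_identical_ages_have_undefined_slope(self):
        with pytest.raises(DegenerateDataError):
            bias_regression([6.0, 6.0, 6.0], [0.1, 0.2, 0.3])
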
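"""The shared statistical engine: odds ratios, chi-square, logistic IRLS,
Breslow-Day homogeneity, Hardy-Weinberg tests."""

from __future__ import annotations

import math

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from episnp import (
    TwoByTwo,
    breslow_day,
    chi2_contingency,
    hwe_chi2,
    hwe_exact,
    logistic_fit,
    lrt,
    or_woolf,
    wald_test,
)
from episnp.exceptions import DegenerateTableError, RankError, SeparationError

from conftest import (
    breslow_day_by_quadratic,
    chi2_by_summation,
    hwe_exact_by_enumeration,
)

cells = st.integers(min_value=1, max_value=500)


class TestOrWoolf:
    def test_published_table_cell(self):
        """AATT vs GGCC in the combined population: OR 4.85 (3.60-6.53)."""
        est = or_woolf(TwoByTwo(148, 141, 131, 605))
        assert round(est.or_value, 2) == 4.85
        assert round(est.ci_low, 2) == 3.60
        assert round(est.ci_high, 2) == 6.53

    def test_symmetric_table_is_null(self):
        assert or_woolf(TwoByTwo(10, 10, 10, 10)).or_value == pytest.approx(1.0)

    def test_haldane_correction(self):
        est = or_woolf(TwoByTwo(5, 0, 10, 10))
        assert est.or_value == pytest.approx((5.5 * 10.5) / (0.5 * 10.5))

    def test_zero_cell_without_correction_errors(self):
        with pytest.raises(DegenerateTableError):
            or_woolf(TwoByTwo(5, 0, 10, 10), correction=False)

    @given(a=cells, b=cells, c=cells, d=cells)
    @settings(max_examples=50, deadline=None)
    def test_antisymmetry(self, a, b, c, d):
        """Swapping exposure labels inverts the OR and mirrors the CI in log scale."""
        t = TwoByTwo(a, b, c, d)
        e1, e2 = or_woolf(t), or_woolf(t.swapped())
        assert e2.or_value == pytest.approx(1.0 / e1.or_value)
        assert e2.ci_low == pytest.approx(1.0 / e1.ci_high)
        assert e2.ci_high == pytest.approx(1.0 / e1.ci_low)


class TestChi2:
    def test_published_allelic_p(self):
        """Discovery allele table reproduces the reported p ~ 1.6e-14."""
        _, df, p = chi2_contingency([[719, 419], [2008, 1984]])
        assert df == 1
        assert math.isclose(math.log10(p), math.log10(1.58e-14), abs_tol=0.1)

    def test_proportional_table_is_null(self):
        stat, _, p = chi2_contingency([[10, 20, 30], [20, 40, 60]])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    @given(st.lists(st.lists(cells, min_size=3, max_size=3), min_size=2, max_size=2))
    @settings(max_examples=30, deadline=None)
    def test_matches_summation_oracle(self, rows):
        stat, _, _ = chi2_contingency(rows)
        assert stat == pytest.approx(chi2_by_summation(rows), rel=1e-10)

    def test_zero_marginal_errors(self):
        with pytest.raises(DegenerateTableError):
            chi2_contingency([[0, 5], [0, 7]])


class TestLogisticFit:
    def expand(self, t: TwoByTwo):
        X = np.array([[1.0, 1.0]] * (t.a + t.b) + [[1.0, 0.0]] * (t.c + t.d))
        y = np.array([1.0] * t.a + [0.0] * t.b + [1.0] * t.c + [0.0] * t.d)
        return X, y

    def test_single_predictor_matches_closed_form_or(self):
        t = TwoByTwo(30, 20, 15, 40)
        X, y = self.expand(t)
        fit = logistic_fit(X, y)
        assert math.exp(fit.coefficients[1]) == pytest.approx(
            or_woolf(t).or_value, abs=1e-6)
        assert fit.converged

    def test_weighted_equals_expanded(self):
        t = TwoByTwo(30, 20, 15, 40)
        X, y = self.expand(t)
        Xw = np.array([[1.0, 1.0], [1.0, 1.0], [1.0, 0.0], [1.0, 0.0]])
        yw = np.array([1.0, 0.0, 1.0, 0.0])
        w = np.array([30.0, 20.0, 15.0, 40.0])
        f1, f2 = logistic_fit(X, y), logistic_fit(Xw, yw, w)
        np.testing.assert_allclose(f1.coefficients, f2.coefficients, atol=1e-8)
        np.testing.assert_allclose(f1.covariance, f2.covariance, atol=1e-8)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-8)

    def test_matches_statsmodels_glm(self):
        rng = np.random.default_rng(11)
        X = np.column_stack([np.ones(400), rng.normal(size=400), rng.integers(0, 3, 400)])
        y = (rng.random(400) < 1 / (1 + np.exp(-(0.3 * X[:, 1] - 0.2 * X[:, 2])))).astype(float)
        ours = logistic_fit(X, y)
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(ours.coefficients, ref.params, atol=1e-7)
        np.testing.assert_allclose(np.sqrt(np.diag(ours.covariance)), ref.bse, atol=1e-6)
        assert ours.loglik == pytest.approx(ref.llf, abs=1e-6)

    def test_constant_response_errors(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.raises(SeparationError):
            logistic_fit(X, np.zeros(10))

    def test_perfect_separation_detected(self):
        X = np.column_stack([np.ones(20), np.r_[np.zeros(10), np.ones(10)]])
        y = np.r_[np.zeros(10), np.ones(10)]
        with pytest.raises(SeparationError):
            logistic_fit(X, y)

    def test_collinear_design_errors(self):
        x = np.arange(12.0)
        X = np.column_stack([np.ones(12), x, 2 * x])
        y = (x > 4).astype(float)
        y[0], y[-1] = 1.0, 0.0
        with pytest.raises((RankError, SeparationError)):
            logistic_fit(X, y)


class TestWaldLrt:
    def test_zero_beta_gives_p_one(self):
        # symmetric 2x2: the slope is exactly zero, so the Wald p is 1
        X = np.array([[1.0, 1.0], [1.0, 1.0], [1.0, 0.0], [1.0, 0.0]])
        y = np.array([1.0, 0.0, 1.0, 0.0])
        fit = logistic_fit(X, y, np.full(4, 10.0))
        _, p = wald_test(fit, 1)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_lrt_identical_models(self):
        assert lrt(-100.0, -100.0, df=4) == pytest.approx(1.0)

    def test_lrt_rejects_inverted_nesting(self):
        with pytest.raises(ValueError):
            lrt(-105.0, -100.0, df=1)

    def test_wald_and_lrt_agree_asymptotically(self):
        """On a large simulated fit the two tests give similar p-values."""
        rng = np.random.default_rng(5)
        n = 10_000
        x = rng.integers(0, 3, n).astype(float)
        p_true = 1 / (1 + np.exp(-(-1.0 + 0.08 * x)))
        y = (rng.random(n) < p_true).astype(float)
        X = np.column_stack([np.ones(n), x])
        full = logistic_fit(X, y)
        reduced = logistic_fit(X[:, :1], y)
        _, p_wald = wald_test(full, 1)
        p_lrt = lrt(full.loglik, reduced.loglik, df=1)
        assert p_wald == pytest.approx(p_lrt, rel=0.2)


class TestBreslowDay:
    def test_identical_strata_are_homogeneous(self):
        strata = [TwoByTwo(20, 30, 10, 40)] * 2
        stat, df, p = breslow_day(strata)
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert df == 1 and p == pytest.approx(1.0)

    @pytest.mark.parametrize("strata", [
        [TwoByTwo(148, 141, 131, 605), TwoByTwo(278, 579, 131, 605)],
        [TwoByTwo(20, 30, 10, 40), TwoByTwo(35, 25, 18, 22), TwoByTwo(9, 14, 21, 8)],
        [TwoByTwo(5, 9, 12, 7), TwoByTwo(13, 4, 6, 15)],
    ])
    def test_matches_quadratic_oracle(self, strata):
        stat, _, _ = breslow_day(strata)
        assert stat == pytest.approx(breslow_day_by_quadratic(strata), abs=1e-8)

    def test_invariant_under_reordering(self):
        strata = [TwoByTwo(20, 30, 10, 40), TwoByTwo(35, 25, 18, 22), TwoByTwo(9, 14, 21, 8)]
        stat1, _, _ = breslow_day(strata)
        stat2, _, _ = breslow_day(strata[::-1])
        assert stat1 == pytest.approx(stat2, rel=1e-12)

    def test_degenerate_stratum_errors(self):
        with pytest.raises(DegenerateTableError):
            breslow_day([TwoByTwo(0, 0, 10, 40), TwoByTwo(20, 30, 10, 40)])

    def test_single_stratum_errors(self):
        with pytest.raises(DegenerateTableError):
            breslow_day([TwoByTwo(20, 30, 10, 40)])


class TestHwe:
    def test_perfect_proportions_chi2(self):
        stat, p = hwe_chi2(25, 50, 25)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("counts", [
        (0, 2, 0), (1, 0, 1), (5, 5, 5), (10, 20, 10), (12, 3, 18), (0, 0, 7),
        (25, 50, 25), (3, 17, 4),
    ])
    def test_exact_matches_enumeration(self, counts):
        assert hwe_exact(*counts) == pytest.approx(
            hwe_exact_by_enumeration(*counts), abs=1e-12)

    @given(st.tuples(st.integers(0, 20), st.integers(0, 20), st.integers(0, 20))
           .filter(lambda t: sum(t) > 0))
    @settings(max_examples=60, deadline=None)
    def test_exact_in_unit_interval_and_matches_oracle(self, counts):
        p = hwe_exact(*counts)
        assert 0.0 <= p <= 1.0
        assert p == pytest.approx(hwe_exact_by_enumeration(*counts), abs=1e-12)

    def test_two_het_sample(self):
        """(0, 2, 0): the modal configuration, exact p = 1."""
        assert hwe_exact(0, 2, 0) == pytest.approx(1.0)

    def test_large_sample_numerically_stable(self):
        """Thousands of genotypes: the exact p stays finite and agrees with
        the chi-square approximation."""
        counts = (2451, 2302, 562)
        p = hwe_exact(*counts)
        _, p_chi = hwe_chi2(*counts)
        assert 0.0 < p <= 1.0
        assert p == pytest.approx(p_chi, abs=0.05)
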
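"""RERI point estimates, MOVER intervals, model equivalence, bootstrap."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from episnp import (
    H1,
    H2,
    H3,
    STANDARD_CONTRASTS,
    ExposureContrast,
    OrEstimate,
    bootstrap_p,
    mover_ci,
    reri_from_counts,
    reri_model,
    reri_point,
)
from episnp.data import load_counts
from episnp.exceptions import DegenerateTableError

from conftest import expand_table_to_cohort


class TestReriPoint:
    def test_published_h2_components(self):
        assert round(reri_point(4.8476, 2.2175, 1.3711), 2) == 2.26

    def test_null_is_zero(self):
        assert reri_point(1, 1, 1) == pytest.approx(0.0)

    def test_exact_risk_additivity(self):
        assert reri_point(3, 2, 2) == pytest.approx(0.0)

    def test_rejects_nonpositive_or(self):
        with pytest.raises(ValueError):
            reri_point(0.0, 1.0, 1.0)


class TestContrasts:
    def test_standard_cell_definitions(self):
        assert H1.cells() == ((0, 0), (1, 0), (0, 1), (1, 1))
        assert H2.cells() == ((0, 0), (2, 0), (0, 2), (2, 2))
        assert H3.cells() == ((1, 1), (2, 1), (1, 2), (2, 2))

    def test_duplicate_cells_rejected(self):
        with pytest.raises(ValueError):
            ExposureContrast("bad", (0, 0), (0, 0), (0, 1), (1, 1))


PUBLISHED_RERI = [
    # (table name, contrast, printed RERI)
    ("rs2106261_rs2200733_combined", "H1", 0.22),
    ("rs2106261_rs2200733_combined", "H2", 2.26),
    ("rs2106261_rs2200733_combined", "H3", 0.99),
    ("rs2106261_rs3807989", "H1", 0.14),
    ("rs2106261_rs3807989", "H2", -1.20),
    ("rs2106261_rs3807989", "H3", 0.16),
    ("rs2200733_rs3807989", "H1", 0.69),
    ("rs2200733_rs3807989", "H2", 1.32),
    ("rs2200733_rs3807989", "H3", 0.13),
]


class TestReriFromCounts:
    @pytest.mark.parametrize("name,contrast,expected", PUBLISHED_RERI)
    def test_reproduces_all_published_unadjusted_reris(self, name, contrast, expected):
        table = load_counts(name)
        res = reri_from_counts(table, STANDARD_CONTRASTS[contrast])
        assert round(res.reri, 2) == expected

    def test_point_identity_with_own_components(self, combined_table):
        res = reri_from_counts(combined_table, H2)
        assert res.reri == pytest.approx(reri_point(
            res.or11.or_value, res.or10.or_value, res.or01.or_value))

    def test_published_h2_mover_interval(self, combined_table):
        """Correlated MOVER interval is close to the reported (1.06, 3.73)."""
        res = reri_from_counts(combined_table, H2)
        assert res.ci_low == pytest.approx(1.06, abs=0.05)
        assert res.ci_high == pytest.approx(3.73, abs=0.05)
        assert res.ci_low <= res.reri <= res.ci_high

    def test_empty_cell_errors(self, spec_a, spec_b):
        import episnp
        counts = np.ones((3, 3, 2), dtype=int)
        counts[2, 2, 1] = 0
        with pytest.raises(DegenerateTableError):
            reri_from_counts(episnp.TwoLocusTable(counts, spec_a, spec_b), H2)


class TestMover:
    def make_est(self, or_value, se):
        return OrEstimate.from_log(np.log(or_value), se)

    def test_zero_correlation_reduces_to_independent_form(self):
        e1, e2, e3 = self.make_est(3.0, 0.2), self.make_est(1.5, 0.15), self.make_est(1.2, 0.3)
        low, high = mover_ci(e1, e2, e3)
        point = reri_point(3.0, 1.5, 1.2)
        l_manual = point - np.sqrt(
            (e1.or_value - e1.ci_low) ** 2 + (e2.ci_high - e2.or_value) ** 2
            + (e3.ci_high - e3.or_value) ** 2)
        assert low == pytest.approx(l_manual)
        assert low < point < high

    @given(
        ors=st.tuples(*[st.floats(0.2, 8.0)] * 3),
        ses=st.tuples(*[st.floats(0.05, 0.6)] * 3),
        rs=st.tuples(*[st.floats(0.0, 0.8)] * 3),
    )
    @settings(max_examples=200, deadline=None)
    def test_interval_contains_point_estimate(self, ors, ses, rs):
        ests = [self.make_est(o, s) for o, s in zip(ors, ses)]
        low, high = mover_ci(*ests, *rs)
        point = reri_point(*ors)
        assert low <= point <= high

    def test_invalid_correlation_rejected(self):
        e = self.make_est(2.0, 0.2)
        with pytest.raises(ValueError):
            mover_ci(e, e, e, r12=1.5)


class TestReriModel:
    def test_count_expanded_equals_closed_form(self, combined_table):
        """The indicator-logistic route reproduces the cross-product route."""
        cohort = expand_table_to_cohort(combined_table)
        for contrast in (H1, H2, H3):
            closed = reri_from_counts(combined_table, contrast)
            model = reri_model(cohort, "rs2106261", "rs2200733", contrast)
            assert model.reri == pytest.approx(closed.reri, abs=1e-6)
            assert model.or11.or_value == pytest.approx(closed.or11.or_value, abs=1e-6)
            assert model.ci_low == pytest.approx(closed.ci_low, abs=1e-4)
            assert model.ci_high == pytest.approx(closed.ci_high, abs=1e-4)

    def test_adjusted_close_to_unadjusted_under_null_covariates(self):
        from episnp.simulate import SimParams, simulate_cohort
        import episnp
        params = SimParams(n_cases=2500, n_controls=2500, interaction=0.3)
        cohort = simulate_cohort(params, seed=21)
        table = episnp.crosstab_pair(cohort, "snpA", "snpB")
        unadj = reri_from_counts(table, H2)
        adj = reri_model(cohort, "snpA", "snpB", H2, covariates=["age", "sex"])
        assert adj.adjusted
        assert adj.reri == pytest.approx(unadj.reri, abs=0.35)


class TestBootstrap:
    def test_same_seed_is_deterministic(self, combined_table):
        p1 = bootstrap_p(combined_table, H2, reps=500, seed=13)
        p2 = bootstrap_p(combined_table, H2, reps=500, seed=13)
        assert p1.p == p2.p and p1.n_degenerate == p2.n_degenerate

    def test_seed_required(self, combined_table):
        with pytest.raises(ValueError):
            bootstrap_p(combined_table, H2, reps=100)

    def test_invariant_to_subject_ordering(self, combined_table):
        """The statistic depends on counts only, so a shuffled cohort gives
        the identical bootstrap p."""
        import episnp
        cohort = expand_table_to_cohort(combined_table)
        rng = np.random.default_rng(4)
        shuffled = episnp.Cohort(
            [cohort.subjects[i] for i in rng.permutation(len(cohort))],
            cohort.specs)
        p1 = bootstrap_p(cohort, H2, reps=400, seed=8,
                         snp_a="rs2106261", snp_b="rs2200733")
        p2 = bootstrap_p(shuffled, H2, reps=400, seed=8,
                         snp_a="rs2106261", snp_b="rs2200733")
        assert p1.p == p2.p

    def test_p_floor_is_one_over_reps(self, combined_table):
        res = bootstrap_p(combined_table, H2, reps=200, seed=2)
        assert res.p >= 1 / 200

    def test_strong_interaction_is_significant(self, combined_table):
        res = bootstrap_p(combined_table, H2, reps=2000, seed=5)
        assert res.p < 0.01
        assert not res.unstable
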
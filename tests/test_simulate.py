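"""The synthetic cohort generator and its exact population oracles."""

from __future__ import annotations

import numpy as np
import pytest

import episnp
from episnp import (
    SimParams,
    build_penetrance,
    hwe_gate,
    reri_point,
    simulate_cohort,
    simulate_table,
)
from episnp.exceptions import ParameterError
from episnp.simulate import recovery_suite


class TestBuildPenetrance:
    def test_hand_computed_additive_matrix(self):
        params = SimParams(mode="risk_additive", baseline=0.01,
                           effect_a=0.01, effect_b=0.01, interaction=0.02)
        pen, _ = build_penetrance(params)
        expected = np.array([
            [0.01, 0.02, 0.03],
            [0.02, 0.05, 0.08],
            [0.03, 0.08, 0.13],
        ])
        np.testing.assert_allclose(pen, expected, atol=1e-12)

    def test_additive_null_has_zero_true_reri_on_risk_scale(self):
        """With no interaction the risk-scale excess is exactly additive; the
        odds-scale RERI deviates only by the rare-disease approximation."""
        params = SimParams(mode="risk_additive", baseline=0.005,
                           effect_a=0.004, effect_b=0.004, interaction=0.0)
        _, true = build_penetrance(params)
        rr = true.rr_matrix
        assert rr[2, 2] - rr[2, 0] - rr[0, 2] + 1 == pytest.approx(0.0, abs=1e-12)
        assert abs(true.reri["H2"]) < 0.05

    def test_multiplicative_null_interaction_or_is_one(self):
        _, true = build_penetrance(SimParams(interaction=0.0))
        assert true.interaction_or == pytest.approx(1.0)

    def test_multiplicative_interaction_or_is_exp_gamma(self):
        _, true = build_penetrance(SimParams(interaction=0.4))
        assert true.interaction_or == pytest.approx(np.exp(0.4))

    def test_true_values_self_consistent(self):
        """reri_point applied to the true ORs equals the stored true RERI."""
        _, true = build_penetrance(SimParams(interaction=0.3))
        for label, contrast in episnp.STANDARD_CONTRASTS.items():
            ref = true.or_matrix[contrast.reference]
            assert true.reri[label] == pytest.approx(reri_point(
                true.or_matrix[contrast.exposed_both] / ref,
                true.or_matrix[contrast.exposed_a] / ref,
                true.or_matrix[contrast.exposed_b] / ref,
            ))

    def test_genotype_frequencies_sum_to_one(self):
        _, true = build_penetrance(SimParams())
        assert true.genotype_freqs.sum() == pytest.approx(1.0)

    def test_rare_disease_or_approximates_rr(self):
        """In the rare-disease regime the OR and RR per genotype agree within
        2%, even in the doubly homozygous cell where risk compounds most."""
        _, true = build_penetrance(SimParams(baseline=0.005))
        np.testing.assert_allclose(true.or_matrix, true.rr_matrix, rtol=0.02)

    def test_out_of_range_penetrance_rejected(self):
        with pytest.raises(ParameterError):
            build_penetrance(SimParams(mode="risk_additive", baseline=0.5,
                                       effect_a=0.2, effect_b=0.2, interaction=0.0))

    def test_invalid_frequency_rejected(self):
        with pytest.raises(ParameterError):
            SimParams(freq_a=1.2)


class TestSimulateCohort:
    def test_same_seed_identical_cohort(self):
        params = SimParams(n_cases=150, n_controls=300)
        c1, c2 = simulate_cohort(params, seed=5), simulate_cohort(params, seed=5)
        for s, t in zip(c1.subjects, c2.subjects):
            assert (s.id, s.sex, s.age, s.status) == (t.id, t.sex, t.age, t.status)
            assert {k: str(v) for k, v in s.calls.items()} == \
                {k: str(v) for k, v in t.calls.items()}

    def test_exact_sample_sizes(self):
        cohort = simulate_cohort(SimParams(n_cases=120, n_controls=250), seed=1)
        assert cohort.n_cases == 120 and cohort.n_controls == 250

    def test_null_effects_balance_allele_frequencies(self):
        """With no genetic effects, case and control risk-allele frequencies
        differ by less than 3 binomial standard errors."""
        params = SimParams(n_cases=5000, n_controls=5000,
                           effect_a=0.0, effect_b=0.0)
        table = simulate_table(params, seed=8)
        for which in ("a", "b"):
            cr, cn, tr, tn = table.marginal(which).allele_counts()
            f_case, f_ctrl = cr / (cr + cn), tr / (tr + tn)
            se = np.sqrt(f_ctrl * (1 - f_ctrl) * (1 / (cr + cn) + 1 / (tr + tn)))
            assert abs(f_case - f_ctrl) < 3 * se

    def test_permuting_subjects_changes_no_statistic(self):
        cohort = simulate_cohort(SimParams(n_cases=200, n_controls=400), seed=12)
        rng = np.random.default_rng(0)
        shuffled = episnp.Cohort(
            [cohort.subjects[i] for i in rng.permutation(len(cohort))],
            cohort.specs)
        t1 = episnp.crosstab_pair(cohort, "snpA", "snpB")
        t2 = episnp.crosstab_pair(shuffled, "snpA", "snpB")
        assert (t1.counts == t2.counts).all()

    def test_cohort_and_table_routes_agree_in_distribution(self):
        """Counts from the subject-level route match the table route's
        generating probabilities (chi-square goodness of fit not rejected)."""
        import scipy.stats
        params = SimParams(n_cases=3000, n_controls=3000)
        cohort = simulate_cohort(params, seed=23)
        table = episnp.crosstab_pair(cohort, "snpA", "snpB")
        pen, true = build_penetrance(params)
        p_case = (true.genotype_freqs * pen).ravel()
        p_case /= p_case.sum()
        stat = ((table.cases.ravel() - 3000 * p_case) ** 2 / (3000 * p_case)).sum()
        assert scipy.stats.chi2.sf(stat, 8) > 0.001

    def test_covariate_effects_shift_case_covariates(self):
        """A positive age effect makes cases older than controls."""
        params = SimParams(n_cases=2000, n_controls=2000, age_effect=0.05)
        cohort = simulate_cohort(params, seed=3)
        ages_case = np.mean([s.age for s in cohort.subjects if s.is_case])
        ages_ctrl = np.mean([s.age for s in cohort.subjects if not s.is_case])
        assert ages_case > ages_ctrl + 2.0

    def test_controls_pass_hwe_gate_calibration(self):
        """Under the generating model, controls fail the HWE gate (p <= 0.01)
        in at most ~1% of simulations; demand >= 98% passing."""
        params = SimParams(n_cases=500, n_controls=2000)
        passed = 0
        for k in range(200):
            table = simulate_table(params, seed=1000 + k)
            if hwe_gate(table.marginal("a")).passed:
                passed += 1
        assert passed >= 196


class TestRecoverySuite:
    def test_summary_structure_and_consistency(self):
        params = SimParams(n_cases=1500, n_controls=2500, interaction=0.3)
        out = recovery_suite(params, n_reps=60, seed=14)
        assert out["n_reps"] == 60
        assert set(out["reri"]) == {"H1", "H2", "H3"}
        for s in out["reri"].values():
            assert 0.0 <= s["ci_coverage"] <= 1.0
        # estimators should sit near their targets even at 60 replicates
        assert abs(out["profile_or22"]["relative_bias"]) < 0.25
        assert out["test5_axa"]["mean_or"] == pytest.approx(
            out["true"]["interaction_or"], rel=0.2)

    def test_rejects_too_few_replicates(self):
        with pytest.raises(ParameterError):
            recovery_suite(SimParams(), n_reps=10, seed=1)
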
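"""Shared fixtures and independent oracle implementations.

The oracles here deliberately re-derive statistics by a different route
than the library (direct enumeration, brute-force summation, quadratic
solution) so that agreement is meaningful.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import settings as hyp_settings

from episnp import Cohort, GenotypeCall, SnpSpec, Subject, TwoByTwo, TwoLocusTable
from episnp.data import load_counts

hyp_settings.register_profile("deterministic", derandomize=True, deadline=None)
hyp_settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def spec_a():
    return SnpSpec("rs2106261", "G", "A")


@pytest.fixture(scope="session")
def spec_b():
    return SnpSpec("rs2200733", "C", "T")


@pytest.fixture(scope="session")
def combined_table():
    return load_counts("rs2106261_rs2200733_combined")


@pytest.fixture(scope="session")
def discovery_table():
    return load_counts("rs2106261_rs2200733_discovery")


def expand_table_to_cohort(table: TwoLocusTable) -> Cohort:
    """Turn a count table into an equivalent subject-level cohort."""
    subjects = []
    k = 0
    for ga in range(3):
        for gb in range(3):
            for status, n in zip((2, 1), table.cell(ga, gb)):
                for _ in range(n):
                    k += 1
                    subjects.append(Subject(
                        f"s{k}", None, None, status,
                        {
                            table.spec_a.name: GenotypeCall.parse(
                                table.spec_a.genotype_label(ga), table.spec_a),
                            table.spec_b.name: GenotypeCall.parse(
                                table.spec_b.genotype_label(gb), table.spec_b),
                        },
                    ))
    return Cohort(subjects, {table.spec_a.name: table.spec_a,
                             table.spec_b.name: table.spec_b})


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def chi2_by_summation(table: np.ndarray) -> float:
    """Pearson statistic as an explicit sum of (O-E)^2/E."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    stat = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            e = table[i].sum() * table[:, j].sum() / total
            stat += (table[i, j] - e) ** 2 / e
    return stat


def hwe_exact_by_enumeration(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact HWE p by full enumeration over heterozygote counts.

    Conditional on sample size and allele counts, the probability of h
    heterozygotes is proportional to n! / (n1! h! n2!) * 2^h.
    """
    n = n_hom_ref + n_het + n_hom_alt
    n_a = 2 * n_hom_ref + n_het  # reference allele count
    probs = {}
    for h in range(min(n_a, 2 * n - n_a) + 1):
        if (n_a - h) % 2:
            continue
        n1 = (n_a - h) // 2
        n2 = n - n1 - h
        if n2 < 0:
            continue
        logp = (
            math.lgamma(n + 1) - math.lgamma(n1 + 1) - math.lgamma(h + 1)
            - math.lgamma(n2 + 1) + h * math.log(2.0)
        )
        probs[h] = math.exp(logp)
    total = sum(probs.values())
    p_obs = probs[n_het] / total
    return min(1.0, sum(v for v in probs.values() if v / total <= p_obs * (1 + 1e-10)) / total)


def breslow_day_by_quadratic(strata: list[TwoByTwo]) -> float:
    """Breslow-Day statistic by solving the expected-cell quadratic directly.

    Against the Mantel-Haenszel common OR psi, the expected a-cell in each
    stratum solves a*(n2 - m1 + a) = psi*(n1 - a)*(m1 - a); the statistic
    sums (a - a_hat)^2 / Var(a_hat).
    """
    num = sum(t.a * t.d / (t.a + t.b + t.c + t.d) for t in strata)
    den = sum(t.b * t.c / (t.a + t.b + t.c + t.d) for t in strata)
    psi = num / den
    stat = 0.0
    for t in strata:
        n1, n2, m1 = t.a + t.b, t.c + t.d, t.a + t.c
        # (psi - 1) a^2 - [psi (n1 + m1) + n2 - m1] a + psi n1 m1 = 0
        qa = psi - 1.0
        qb = -(psi * (n1 + m1) + (n2 - m1))
        qc = psi * n1 * m1
        if abs(qa) < 1e-12:
            a_hat = -qc / qb
        else:
            disc = math.sqrt(qb * qb - 4 * qa * qc)
            roots = [(-qb + disc) / (2 * qa), (-qb - disc) / (2 * qa)]
            a_hat = next(r for r in roots if 0 < r < min(n1, m1) + 1e-9)
        var = 1.0 / (1.0 / a_hat + 1.0 / (n1 - a_hat) + 1.0 / (m1 - a_hat)
                     + 1.0 / (n2 - m1 + a_hat))
        stat += (t.a - a_hat) ** 2 / var
    return stat
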
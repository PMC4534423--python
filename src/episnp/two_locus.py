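"""Two-locus genotype odds-ratio profiles and their comparisons.

For a SNP pair the nine joint genotypes are profiled against a reference
genotype (by default the doubly non-risk homozygote): counts, column
percentages, cross-product ORs with Woolf intervals and Pearson p-values,
and -- when subject-level data are available -- covariate-adjusted ORs
from a single logistic model with eight genotype indicators.

Breslow-Day homogeneity compares the ORs of two genotype cells, each
taken against the shared reference cell, and the synergy summary contrasts
the doubly risk-homozygous OR with the sum of the two single-risk
homozygote ORs (a risk-additivity benchmark; the multiplicative product
is also reported for completeness).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import io
from .exceptions import MissingCovariateError, ReferenceDegenerateError
from .single_locus import _covariate_columns
from .stats import OrEstimate, TwoByTwo, breslow_day, logistic_fit, or_woolf, wald_test


@dataclass
class GenotypeOrProfile:
    table: io.TwoLocusTable
    reference: tuple[int, int]
    rows: pd.DataFrame
    adjusted: bool = False
    covariates: tuple[str, ...] = ()

    def estimate(self, genotype: tuple[int, int], adjusted: bool = False) -> OrEstimate:
        """OrEstimate for one joint-dosage genotype cell."""
        r = self.rows[(self.rows.dosage_a == genotype[0]) & (self.rows.dosage_b == genotype[1])]
        if r.empty:
            raise KeyError(f"genotype {genotype} not in profile")
        r = r.iloc[0]
        prefix = "adj_" if adjusted else ""
        if adjusted and not self.adjusted:
            raise ValueError("profile carries no adjusted estimates")
        return OrEstimate(
            r[f"{prefix}or"], r[f"{prefix}ci_low"], r[f"{prefix}ci_high"],
            float(np.log(r[f"{prefix}or"])), float("nan"), r[f"{prefix}p"],
        )


def genotype_or_profile(
    table: io.TwoLocusTable,
    reference: tuple[int, int] = (0, 0),
    cohort: io.Cohort | None = None,
    covariates: Sequence[str] = ("age", "sex"),
) -> GenotypeOrProfile:
    """Profile all nine two-locus genotypes against a reference cell.

    When *cohort* is given, adjusted ORs are added from one logistic fit of
    status on eight genotype indicators plus the covariates.
    """
    ref_cases, ref_controls = table.cell(*reference)
    if ref_cases == 0 or ref_controls == 0:
        alternatives = [
            g for g in io.GENOTYPE_ORDER
            if table.cell(*g)[0] > 0 and table.cell(*g)[1] > 0
        ]
        raise ReferenceDegenerateError(
            f"reference genotype {table.genotype_label(*reference)} empty in cases or "
            f"controls; non-empty candidates: "
            f"{[table.genotype_label(*g) for g in alternatives[:3]]}"
        )

    n_cases, n_controls = table.n_cases, table.n_controls
    rows = []
    for ga, gb in io.GENOTYPE_ORDER:
        nc, nn = table.cell(ga, gb)
        row = {
            "genotype_a": table.spec_a.genotype_label(ga),
            "genotype_b": table.spec_b.genotype_label(gb),
            "dosage_a": ga,
            "dosage_b": gb,
            "n_cases": nc,
            "pct_cases": 100.0 * nc / n_cases if n_cases else 0.0,
            "n_controls": nn,
            "pct_controls": 100.0 * nn / n_controls if n_controls else 0.0,
        }
        if (ga, gb) == reference:
            est = OrEstimate.identity()
        else:
            est = or_woolf(TwoByTwo(nc, nn, ref_cases, ref_controls))
        row.update({"or": est.or_value, "ci_low": est.ci_low,
                    "ci_high": est.ci_high, "p": est.p})
        rows.append(row)
    df = pd.DataFrame(rows)

    adjusted = False
    cov_used: tuple[str, ...] = ()
    if cohort is not None:
        df = _adjusted_columns(df, table, reference, cohort, covariates)
        adjusted = True
        cov_used = tuple(covariates)
    return GenotypeOrProfile(table, reference, df, adjusted, cov_used)


def _adjusted_columns(df, table, reference, cohort, covariates):
    spec_a, spec_b = table.spec_a, table.spec_b
    subjects = []
    cells = []
    for s in cohort.subjects:
        da = io.dosage(s.calls.get(spec_a.name, io.GenotypeCall.missing()), spec_a)
        db = io.dosage(s.calls.get(spec_b.name, io.GenotypeCall.missing()), spec_b)
        if da is None or db is None:
            continue
        subjects.append(s)
        cells.append((da, db))
    non_ref = [g for g in io.GENOTYPE_ORDER if g != reference]
    indicators = np.array([[1.0 if c == g else 0.0 for g in non_ref] for c in cells])
    y = np.array([1.0 if s.is_case else 0.0 for s in subjects])
    cov_x, cov_names = _covariate_columns(subjects, covariates)
    X = np.column_stack([np.ones_like(y), indicators, cov_x])
    names = ["intercept"] + [table.genotype_label(*g) for g in non_ref] + cov_names
    fit = logistic_fit(X, y, names=names)

    adj = {g: fit.term(1 + i) for i, g in enumerate(non_ref)}
    for col in ("adj_or", "adj_ci_low", "adj_ci_high", "adj_p"):
        df[col] = np.nan
    for idx, row in df.iterrows():
        g = (row.dosage_a, row.dosage_b)
        if g == reference:
            df.loc[idx, "adj_or"] = 1.0
            continue
        est = adj[g]
        _, p = wald_test(fit, 1 + non_ref.index(g))
        df.loc[idx, ["adj_or", "adj_ci_low", "adj_ci_high", "adj_p"]] = (
            est.or_value, est.ci_low, est.ci_high, p)
    return df


def compare_genotype_ors(
    table: io.TwoLocusTable,
    genotype_1: tuple[int, int],
    genotype_2: tuple[int, int],
    reference: tuple[int, int] = (0, 0),
    tarone: bool = False,
) -> tuple[float, float]:
    """Breslow-Day comparison of two genotype-vs-reference odds ratios.

    The two strata are the genotype-vs-reference 2x2 tables; the reference
    cell's counts appear in both strata.  Returns (statistic, p).
    """
    if reference in (genotype_1, genotype_2):
        raise ValueError("compared genotypes must differ from the reference")
    ref_c, ref_n = table.cell(*reference)
    strata = []
    for g in (genotype_1, genotype_2):
        nc, nn = table.cell(*g)
        strata.append(TwoByTwo(nc, nn, ref_c, ref_n))
    stat, _, p = breslow_day(strata, tarone=tarone)
    return stat, p


@dataclass
class SynergySummary:
    or_both: float  # doubly risk-homozygous genotype
    or_a_only: float  # risk homozygote at SNP A only
    or_b_only: float  # risk homozygote at SNP B only
    sum_single: float
    exceeds_sum: bool
    product_single: float  # multiplicative benchmark (extension)
    exceeds_product: bool
    bd_p_vs_a_only: float
    bd_p_vs_b_only: float
    adjusted: bool


def synergy_summary(profile: GenotypeOrProfile, use_adjusted: bool | None = None) -> SynergySummary:
    """Contrast the doubly risk-homozygous OR with the single-risk homozygotes.

    The headline comparison is against the SUM of the two single-risk
    homozygote ORs (additivity of excess relative odds); the product is
    reported alongside as the conventional multiplicative benchmark.
    """
    if use_adjusted is None:
        use_adjusted = profile.adjusted
    or_both = profile.estimate((2, 2), adjusted=use_adjusted).or_value
    or_a = profile.estimate((2, 0), adjusted=use_adjusted).or_value
    or_b = profile.estimate((0, 2), adjusted=use_adjusted).or_value
    _, p_a = compare_genotype_ors(profile.table, (2, 2), (2, 0), profile.reference)
    _, p_b = compare_genotype_ors(profile.table, (2, 2), (0, 2), profile.reference)
    return SynergySummary(
        or_both, or_a, or_b,
        sum_single=or_a + or_b,
        exceeds_sum=or_both > or_a + or_b,
        product_single=or_a * or_b,
        exceeds_product=or_both > or_a * or_b,
        bd_p_vs_a_only=p_a,
        bd_p_vs_b_only=p_b,
        adjusted=use_adjusted,
    )
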
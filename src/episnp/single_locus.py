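"""Per-SNP association: allelic and genotypic tests, genetic-model odds
ratios (additive / dominant / recessive), and the Hardy-Weinberg gate
applied to control genotypes."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.stats

from . import io
from .exceptions import MissingCovariateError
from .stats import (
    OrEstimate,
    TwoByTwo,
    chi2_contingency,
    hwe_chi2,
    hwe_exact,
    logistic_fit,
    or_woolf,
    wald_test,
)

MODELS = ("additive", "dominant", "recessive")


@dataclass
class AssociationResult:
    snp: str
    test: str  # allelic | genotypic-2x3 | additive | dominant | recessive
    p: float
    estimate: OrEstimate | None = None
    adjusted: bool = False
    covariates: tuple[str, ...] = ()
    n_cases: int = 0
    n_controls: int = 0


def allelic_association(counts: io.GenotypeCounts) -> AssociationResult:
    """Allele-based 2x2 association with the risk allele as exposure."""
    cr, cn, tr, tn = counts.allele_counts()
    est = or_woolf(TwoByTwo(cr, tr, cn, tn))
    return AssociationResult(
        counts.snp, "allelic", est.p, est,
        n_cases=counts.n_cases, n_controls=counts.n_controls,
    )


def genotypic_association(counts: io.GenotypeCounts) -> AssociationResult:
    """2x3 genotypic Pearson chi-square (2 df, no OR)."""
    table = np.vstack([counts.cases, counts.controls])
    _, _, p = chi2_contingency(table)
    return AssociationResult(
        counts.snp, "genotypic-2x3", p,
        n_cases=counts.n_cases, n_controls=counts.n_controls,
    )


def cochran_armitage_trend(counts: io.GenotypeCounts) -> float:
    """1-df Cochran-Armitage trend p with dosage scores 0/1/2."""
    scores = np.array([0.0, 1.0, 2.0])
    cases, controls = counts.cases.astype(float), counts.controls.astype(float)
    n = cases.sum() + controls.sum()
    tot = cases + controls
    diff = float((scores * (cases - cases.sum() / n * tot)).sum())
    pbar = cases.sum() / n
    var = pbar * (1 - pbar) * (
        float((scores**2 * tot).sum()) - float((scores * tot).sum()) ** 2 / n
    )
    if var <= 0:
        return 1.0
    z = diff / np.sqrt(var)
    return float(2.0 * scipy.stats.norm.sf(abs(z)))


def _covariate_columns(subjects, covariates: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    cols, names = [], []
    for cov in covariates:
        if cov == "age":
            ages = [s.age for s in subjects]
            if any(a is None for a in ages):
                raise MissingCovariateError("age missing for some subjects")
            cols.append(np.array(ages, dtype=float))
            names.append("age")
        elif cov == "sex":
            sexes = [s.sex for s in subjects]
            if any(x is None for x in sexes):
                raise MissingCovariateError("sex missing for some subjects")
            cols.append(np.array(sexes, dtype=float) - 1.0)  # 0 = male, 1 = female
            names.append("sex")
        else:
            raise MissingCovariateError(f"unknown covariate {cov!r}")
    return (np.column_stack(cols) if cols else np.empty((len(subjects), 0)), names)


def model_association(
    data: io.GenotypeCounts | io.Cohort,
    model: str,
    snp: str | None = None,
    covariates: Sequence[str] | None = None,
    trend: bool = False,
) -> AssociationResult:
    """Genetic-model association for one SNP.

    dominant: carriers (dosage >= 1) vs non-carriers as a 2x2;
    recessive: risk homozygotes (dosage = 2) vs the rest;
    additive: logistic regression on dosage (per-allele OR), optionally a
    Cochran-Armitage trend p instead (*trend*, unadjusted counts only).
    Covariate adjustment (age/sex) requires subject-level data.
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    if covariates and not isinstance(data, io.Cohort):
        raise MissingCovariateError("covariate adjustment needs subject-level data")

    if isinstance(data, io.Cohort):
        if snp is None:
            raise ValueError("snp name required with cohort input")
        counts = io.crosstab_single(data, snp)
    else:
        counts = data
        snp = counts.snp

    if model in ("dominant", "recessive") and not covariates:
        if model == "dominant":
            a, b = counts.cases[1] + counts.cases[2], counts.controls[1] + counts.controls[2]
            c, d = counts.cases[0], counts.controls[0]
        else:
            a, b = counts.cases[2], counts.controls[2]
            c, d = counts.cases[0] + counts.cases[1], counts.controls[0] + counts.controls[1]
        est = or_woolf(TwoByTwo(int(a), int(b), int(c), int(d)))
        return AssociationResult(snp, model, est.p, est,
                                 n_cases=counts.n_cases, n_controls=counts.n_controls)

    if trend and model == "additive" and not covariates:
        return AssociationResult(snp, "additive-trend", cochran_armitage_trend(counts),
                                 n_cases=counts.n_cases, n_controls=counts.n_controls)

    # regression route (additive always; dominant/recessive when adjusted)
    code = {
        "additive": lambda d: float(d),
        "dominant": lambda d: 1.0 if d >= 1 else 0.0,
        "recessive": lambda d: 1.0 if d == 2 else 0.0,
    }[model]
    names = ["intercept", model]
    if covariates:
        subjects = [
            s for s in data.subjects
            if io.dosage(s.calls.get(snp, io.GenotypeCall.missing()), data.specs[snp]) is not None
        ]
        dosages = np.array([
            code(io.dosage(s.calls[snp], data.specs[snp])) for s in subjects
        ])
        y = np.array([1.0 if s.is_case else 0.0 for s in subjects])
        cov_x, cov_names = _covariate_columns(subjects, covariates)
        X = np.column_stack([np.ones_like(y), dosages, cov_x])
        names += cov_names
        fit = logistic_fit(X, y, names=names)
    else:
        rows, ys, ws = [], [], []
        for d in range(3):
            rows += [[1.0, code(d)]] * 2
            ys += [1.0, 0.0]
            ws += [counts.cases[d], counts.controls[d]]
        fit = logistic_fit(np.array(rows), np.array(ys), np.array(ws, dtype=float), names=names)
    est = fit.term(1)
    _, p = wald_test(fit, 1)
    return AssociationResult(
        snp, model, p, est, adjusted=bool(covariates),
        covariates=tuple(covariates or ()),
        n_cases=counts.n_cases, n_controls=counts.n_controls,
    )


@dataclass
class HweGate:
    snp: str
    p: float
    passed: bool
    threshold: float
    method: str


def hwe_gate(
    counts: io.GenotypeCounts,
    threshold: float = 0.01,
    method: str = "exact",
) -> HweGate:
    """Hardy-Weinberg gate on control genotypes: fail when p <= threshold.

    A failure is a reportable quality flag, not a fatal error.
    """
    n0, n1, n2 = (int(x) for x in counts.controls)
    if method == "exact":
        p = hwe_exact(n0, n1, n2)
    elif method == "chi2":
        _, p = hwe_chi2(n0, n1, n2)
    else:
        raise ValueError("method must be 'exact' or 'chi2'")
    return HweGate(counts.snp, p, p > threshold, threshold, method)
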
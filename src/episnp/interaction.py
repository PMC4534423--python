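"""Genotypic interaction by logistic regression (Cordell-Clayton partition).

Each SNP contributes an additive term x (coded-allele dosage 0/1/2) and a
dominance term z (heterozygote indicator 0/1/0).  The full genotypic
interaction model adds the four cross-products

    status ~ xA + zA + xB + zB + xA*xB + xA*zB + zA*xB + zA*zB

(the "4-df" genotypic interaction test); the reduced additive-interaction
model keeps only the additive terms and their single product

    status ~ xA + xB + xA*xB

(additive-by-additive interaction on the multiplicative odds scale).
Per-term odds ratios use Wald intervals; the global interaction test is a
likelihood-ratio test of the full model against its main-effects submodel.

Orientation of the additive dosage: by default the coded allele is the
MINOR allele of each SNP in the analysed sample -- the convention of the
interaction software this model family is known from, and the one that
makes the dominance terms' pairing reproducible.  The dominance indicator
is orientation-invariant; flipping one SNP's coded allele inverts the
A-by-A and the mixed-term odds ratios but leaves every p-value and the
global test unchanged.  Risk-allele orientation is available via
:class:`CodingScheme`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import io
from .exceptions import MissingCovariateError
from .single_locus import _covariate_columns
from .stats import LogisticFit, OrEstimate, logistic_fit, lrt, wald_test

TERM_NAMES = ("AxA", "AxD", "DxA", "DxD")


@dataclass(frozen=True)
class CodingScheme:
    """How each SNP's genotype enters the design.

    orientation: "minor" codes the additive dosage as the count of the
    sample-minor allele; "risk" counts the declared risk allele.  The
    dominance coding is the heterozygote indicator in either case.
    """

    orientation: str = "minor"

    def __post_init__(self) -> None:
        if self.orientation not in ("minor", "risk"):
            raise ValueError("orientation must be 'minor' or 'risk'")


@dataclass
class TermResult:
    name: str
    estimate: OrEstimate
    p: float


@dataclass
class InteractionFit:
    terms: dict[str, TermResult]
    main_effects: dict[str, float]  # coefficient values of the main-effect terms
    global_p: float
    global_df: int
    loglik_full: float
    loglik_main: float
    n_params_full: int
    adjusted: bool
    covariates: tuple[str, ...]
    coding: CodingScheme
    flipped: tuple[bool, bool]  # whether each SNP's dosage was flipped to the minor allele
    n_cases: int
    n_controls: int
    fit: LogisticFit = field(repr=False, default=None)


def _risk_allele_is_major(table: io.TwoLocusTable, which: str) -> bool:
    counts = table.marginal(which)
    cr, cn, tr, tn = counts.allele_counts()
    return (cr + tr) > (cn + tn)


def _design_rows(
    data: io.TwoLocusTable | io.Cohort,
    snp_a: str | None,
    snp_b: str | None,
    coding: CodingScheme,
    covariates: Sequence[str],
):
    """Expanded (X columns dict, y, weights, subjects, flips) for either input kind."""
    if isinstance(data, io.Cohort):
        if snp_a is None or snp_b is None:
            raise ValueError("snp names required with cohort input")
        table = io.crosstab_pair(data, snp_a, snp_b)
    else:
        if covariates:
            raise MissingCovariateError("covariate adjustment needs subject-level data")
        table = data

    flip_a = coding.orientation == "minor" and _risk_allele_is_major(table, "a")
    flip_b = coding.orientation == "minor" and _risk_allele_is_major(table, "b")

    def coded(ga: int, gb: int) -> tuple[float, float, float, float]:
        xa = float(2 - ga if flip_a else ga)
        xb = float(2 - gb if flip_b else gb)
        return xa, float(ga == 1), xb, float(gb == 1)

    if isinstance(data, io.Cohort) and covariates:
        spec_a, spec_b = data.specs[snp_a], data.specs[snp_b]
        subjects, gcols = [], []
        for s in data.subjects:
            da = io.dosage(s.calls.get(snp_a, io.GenotypeCall.missing()), spec_a)
            db = io.dosage(s.calls.get(snp_b, io.GenotypeCall.missing()), spec_b)
            if da is None or db is None:
                continue
            subjects.append(s)
            gcols.append(coded(da, db))
        G = np.array(gcols)
        y = np.array([1.0 if s.is_case else 0.0 for s in subjects])
        w = None
        cov_x, cov_names = _covariate_columns(subjects, covariates)
    else:
        rows, ys, ws = [], [], []
        for ga, gb in io.GENOTYPE_ORDER:
            nc, nn = table.cell(ga, gb)
            rows += [coded(ga, gb)] * 2
            ys += [1.0, 0.0]
            ws += [nc, nn]
        G, y, w = np.array(rows), np.array(ys), np.array(ws, dtype=float)
        cov_x, cov_names = np.empty((len(ys), 0)), []
    return G, y, w, cov_x, cov_names, (flip_a, flip_b), table


def _assemble(G, cov_x, interactions: Sequence[tuple[int, int]], main_idx: Sequence[int]):
    xa, za, xb, zb = G[:, 0], G[:, 1], G[:, 2], G[:, 3]
    cols = [np.ones(G.shape[0])] + [G[:, i] for i in main_idx]
    for i, j in interactions:
        cols.append(G[:, i] * G[:, j])
    return np.column_stack(cols + [cov_x]) if cov_x.size else np.column_stack(cols)


def interaction_test6(
    data: io.TwoLocusTable | io.Cohort,
    coding: CodingScheme = CodingScheme(),
    covariates: Sequence[str] = (),
    snp_a: str | None = None,
    snp_b: str | None = None,
) -> InteractionFit:
    """Full genotypic-interaction fit: A/D main effects plus the four
    interaction cross-products; 4-df global likelihood-ratio test."""
    G, y, w, cov_x, cov_names, flips, table = _design_rows(data, snp_a, snp_b, coding, covariates)
    main_idx = (0, 1, 2, 3)
    products = ((0, 2), (0, 3), (1, 2), (1, 3))  # xa*xb, xa*zb, za*xb, za*zb
    main_names = ["xA", "zA", "xB", "zB"]
    names = ["intercept"] + main_names + list(TERM_NAMES) + cov_names
    X_full = _assemble(G, cov_x, products, main_idx)
    fit_full = logistic_fit(X_full, y, w, names=names)
    X_main = _assemble(G, cov_x, (), main_idx)
    fit_main = logistic_fit(X_main, y, w, names=["intercept"] + main_names + cov_names)

    terms = {}
    for k, term in enumerate(TERM_NAMES):
        idx = 5 + k
        est = fit_full.term(idx)
        _, p = wald_test(fit_full, idx)
        terms[term] = TermResult(term, est, p)
    global_p = lrt(fit_full.loglik, fit_main.loglik, df=4)
    return InteractionFit(
        terms,
        {n: float(fit_full.coefficients[1 + i]) for i, n in enumerate(main_names)},
        global_p, 4, fit_full.loglik, fit_main.loglik, X_full.shape[1],
        bool(covariates), tuple(covariates), coding, flips,
        table.n_cases, table.n_controls, fit=fit_full,
    )


def interaction_test5(
    data: io.TwoLocusTable | io.Cohort,
    coding: CodingScheme = CodingScheme(),
    covariates: Sequence[str] = (),
    snp_a: str | None = None,
    snp_b: str | None = None,
) -> InteractionFit:
    """Additive-by-additive interaction on the multiplicative odds scale
    (dominance terms removed): status ~ xA + xB + xA*xB."""
    G, y, w, cov_x, cov_names, flips, table = _design_rows(data, snp_a, snp_b, coding, covariates)
    main_idx = (0, 2)  # xa, xb
    names = ["intercept", "xA", "xB", "AxA"] + cov_names
    X_full = _assemble(G, cov_x, ((0, 2),), main_idx)
    fit_full = logistic_fit(X_full, y, w, names=names)
    X_main = _assemble(G, cov_x, (), main_idx)
    fit_main = logistic_fit(X_main, y, w, names=["intercept", "xA", "xB"] + cov_names)

    est = fit_full.term(3)
    _, p = wald_test(fit_full, 3)
    global_p = lrt(fit_full.loglik, fit_main.loglik, df=1)
    return InteractionFit(
        {"AxA": TermResult("AxA", est, p)},
        {"xA": float(fit_full.coefficients[1]), "xB": float(fit_full.coefficients[2])},
        global_p, 1, fit_full.loglik, fit_main.loglik, X_full.shape[1],
        bool(covariates), tuple(covariates), coding, flips,
        table.n_cases, table.n_controls, fit=fit_full,
    )


def dominance_reduction_lrt(fit_full: InteractionFit, fit_reduced: InteractionFit) -> tuple[float, int]:
    """Goodness-of-fit loss from dropping dominance terms.

    Likelihood-ratio test of the full genotypic-interaction model against
    the reduced (additive-only) model fitted on the same data; both models
    are passed explicitly and the df is the difference in parameter counts.
    """
    if (fit_full.n_cases, fit_full.n_controls) != (fit_reduced.n_cases, fit_reduced.n_controls):
        raise ValueError("models were fitted on different data")
    df = fit_full.n_params_full - fit_reduced.n_params_full
    if df <= 0:
        raise ValueError("reduced model is not nested in the full model")
    return lrt(fit_full.loglik_full, fit_reduced.loglik_full, df), df
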
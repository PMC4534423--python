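"""Shared statistical engine.

Contingency machinery (Woolf odds-ratio intervals, Pearson chi-square),
a frequency-weighted Newton/IRLS logistic regression, Wald and
likelihood-ratio tests, Breslow-Day odds-ratio homogeneity, and exact /
chi-square Hardy-Weinberg tests.

Conventions: confidence intervals are 95% Wald intervals on the log-odds
scale (z = 1.96); Pearson chi-square statistics carry no continuity
correction; the logistic fitter declares convergence when the relative
log-likelihood change falls below 1e-10 (at most 100 iterations) starting
from zero coefficients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.special
import scipy.stats
from statsmodels.stats.contingency_tables import StratifiedTable

from .exceptions import DegenerateTableError, RankError, SeparationError

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class TwoByTwo:
    """Exposure-oriented 2x2 case-control table.

    a: exposed cases, b: exposed controls, c: reference cases,
    d: reference controls.  The odds ratio is (a*d)/(b*c).
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")
        if self.a + self.b + self.c + self.d == 0:
            raise DegenerateTableError("empty 2x2 table")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    def swapped(self) -> "TwoByTwo":
        """Exposure and reference labels exchanged (inverts the OR)."""
        return TwoByTwo(self.c, self.d, self.a, self.b)


@dataclass(frozen=True)
class OrEstimate:
    """An odds ratio with its Woolf 95% CI and association p-value."""

    or_value: float
    ci_low: float
    ci_high: float
    log_or: float
    se_log_or: float
    p: float

    @classmethod
    def identity(cls) -> "OrEstimate":
        """The reference category's degenerate estimate (OR 1, no interval)."""
        return cls(1.0, float("nan"), float("nan"), 0.0, float("nan"), float("nan"))

    @classmethod
    def from_log(cls, log_or: float, se: float, p: float | None = None) -> "OrEstimate":
        if p is None:
            z = log_or / se if se > 0 else 0.0
            p = 2.0 * scipy.stats.norm.sf(abs(z))
        return cls(
            math.exp(log_or),
            math.exp(log_or - Z95 * se),
            math.exp(log_or + Z95 * se),
            log_or,
            se,
            float(p),
        )


def chi2_contingency(table: np.ndarray | Sequence[Sequence[float]]) -> tuple[float, int, float]:
    """Pearson chi-square without continuity correction on an r x c table."""
    arr = np.asarray(table, dtype=float)
    if (arr < 0).any():
        raise ValueError("negative count")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise DegenerateTableError("zero marginal in contingency table")
    stat, p, dof, _ = scipy.stats.chi2_contingency(arr, correction=False)
    return float(stat), int(dof), float(p)


def or_woolf(t: TwoByTwo, correction: bool = True) -> OrEstimate:
    """Cross-product odds ratio with Woolf (log-scale Wald) 95% CI.

    With any zero cell and *correction* enabled, 0.5 is added to all four
    cells (Haldane-Anscombe) before computing the OR and its interval; the
    association p-value always comes from the Pearson chi-square on the
    original table.
    """
    cells = np.array([t.a, t.b, t.c, t.d], dtype=float)
    arr = t.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise DegenerateTableError("zero row or column in 2x2 table")
    if (cells == 0).any():
        if not correction:
            raise DegenerateTableError("zero cell with continuity correction disabled")
        cells = cells + 0.5
    a, b, c, d = cells
    log_or = math.log(a * d) - math.log(b * c)
    se = math.sqrt((1.0 / cells).sum())
    _, _, p = chi2_contingency(arr)
    return OrEstimate.from_log(log_or, se, p)


# ---------------------------------------------------------------------------
# logistic regression (Newton / IRLS with frequency weights)
# ---------------------------------------------------------------------------

@dataclass
class LogisticFit:
    coefficients: np.ndarray
    covariance: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    names: list[str]

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))

    def term(self, index: int) -> OrEstimate:
        """Wald OR estimate for one coefficient."""
        return OrEstimate.from_log(float(self.coefficients[index]), float(self.se[index]))


_BETA_DIVERGENCE = 15.0  # |log-odds| beyond this flags separation


def _loglik(eta: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    # y*eta - log(1 + e^eta), numerically stable
    return float(np.sum(w * (y * eta - np.logaddexp(0.0, eta))))


def logistic_fit(
    design: np.ndarray,
    response: np.ndarray,
    weights: np.ndarray | None = None,
    names: Sequence[str] | None = None,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> LogisticFit:
    """Maximum-likelihood logistic regression by Newton/IRLS.

    *weights* are frequency (replicate) weights, so a fit on aggregated
    count data is identical to a fit on the expanded records.  Raises
    :class:`SeparationError` when coefficients diverge and
    :class:`RankError` for a singular information matrix or a constant
    non-intercept column.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(response, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("design rows must match response length")
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise ValueError("negative weight")
    names = list(names) if names is not None else [f"x{j}" for j in range(X.shape[1])]

    constant = [j for j in range(X.shape[1]) if np.ptp(X[:, j]) == 0.0]
    if len(constant) > 1:
        raise RankError(f"constant non-intercept column {names[constant[1]]!r}")

    total_cases = float(np.sum(w * y))
    if total_cases == 0 or total_cases == float(np.sum(w)):
        raise SeparationError("response is constant (all cases or all controls)")

    beta = np.zeros(X.shape[1])
    ll = _loglik(X @ beta, y, w)
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        eta = X @ beta
        mu = scipy.special.expit(eta)
        wvar = w * mu * (1.0 - mu)
        score = X.T @ (w * (y - mu))
        info = X.T @ (X * wvar[:, None])
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            raise RankError(_name_singular(info, names)) from None
        # step-halving to guarantee a likelihood ascent
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new = _loglik(X @ cand, y, w)
            if ll_new >= ll - 1e-12:
                break
            factor /= 2.0
        beta = beta + factor * step
        if np.max(np.abs(beta)) > _BETA_DIVERGENCE:
            j = int(np.argmax(np.abs(beta)))
            raise SeparationError(f"coefficient for {names[j]!r} diverges: separation")
        if abs(ll_new - ll) < tol * (abs(ll) + 1.0):
            ll = ll_new
            converged = True
            break
        ll = ll_new

    eta = X @ beta
    mu = scipy.special.expit(eta)
    if np.max(np.abs(beta)) > _BETA_DIVERGENCE:
        j = int(np.argmax(np.abs(beta)))
        raise SeparationError(f"coefficient for {names[j]!r} diverges: separation")
    info = X.T @ (X * (w * mu * (1.0 - mu))[:, None])
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        raise RankError(_name_singular(info, names)) from None
    return LogisticFit(beta, cov, ll, n_iter, converged, names)


def _name_singular(info: np.ndarray, names: Sequence[str]) -> str:
    eigvals, eigvecs = np.linalg.eigh(info)
    j = int(np.argmax(np.abs(eigvecs[:, np.argmin(np.abs(eigvals))])))
    return f"singular information matrix; column {names[j]!r} implicated"


def wald_test(fit: LogisticFit, index: int) -> tuple[float, float]:
    """Wald z statistic and two-sided p for one coefficient."""
    se = fit.se[index]
    z = float(fit.coefficients[index] / se) if se > 0 else 0.0
    return z, float(2.0 * scipy.stats.norm.sf(abs(z)))


def lrt(ll_full: float, ll_reduced: float, df: int) -> float:
    """Likelihood-ratio chi-square p-value for nested models."""
    if ll_full < ll_reduced - 1e-6:
        raise ValueError("full model log-likelihood below reduced model")
    stat = max(0.0, 2.0 * (ll_full - ll_reduced))
    return float(scipy.stats.chi2.sf(stat, df))


# ---------------------------------------------------------------------------
# Breslow-Day homogeneity
# ---------------------------------------------------------------------------

def breslow_day(strata: Sequence[TwoByTwo], tarone: bool = False) -> tuple[float, int, float]:
    """Breslow-Day test of odds-ratio homogeneity across 2x2 strata.

    Tests each stratum's OR against the Mantel-Haenszel common OR;
    df = K - 1.  *tarone* applies the Tarone adjustment.
    """
    if len(strata) < 2:
        raise DegenerateTableError("Breslow-Day needs at least two strata")
    for k, t in enumerate(strata):
        arr = t.as_array()
        if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
            raise DegenerateTableError(f"stratum {k} has a zero marginal")
    stacked = np.dstack([t.as_array() for t in strata])
    with np.errstate(divide="ignore", invalid="ignore"):
        result = StratifiedTable(stacked).test_equal_odds(adjust=tarone)
    stat, p = float(result.statistic), float(result.pvalue)
    if math.isnan(stat):
        # the expected-cell quadratic degenerates when the common OR is 1
        stat = _breslow_day_direct(strata)
        p = float(scipy.stats.chi2.sf(stat, len(strata) - 1))
    return stat, len(strata) - 1, p


def _breslow_day_direct(strata: Sequence[TwoByTwo]) -> float:
    """Breslow-Day statistic with explicit handling of a unit common OR."""
    n = [t.a + t.b + t.c + t.d for t in strata]
    psi_num = sum(t.a * t.d / nk for t, nk in zip(strata, n))
    psi_den = sum(t.b * t.c / nk for t, nk in zip(strata, n))
    psi = psi_num / psi_den
    stat = 0.0
    for t in strata:
        n1, n2, m1 = t.a + t.b, t.c + t.d, t.a + t.c
        qa, qb, qc = psi - 1.0, -(psi * (n1 + m1) + (n2 - m1)), psi * n1 * m1
        if abs(qa) < 1e-10:
            a_hat = -qc / qb
        else:
            disc = math.sqrt(qb * qb - 4 * qa * qc)
            roots = ((-qb + disc) / (2 * qa), (-qb - disc) / (2 * qa))
            a_hat = next(r for r in roots if 0 < r < min(n1, m1) + 1e-9)
        var = 1.0 / (1.0 / a_hat + 1.0 / (n1 - a_hat) + 1.0 / (m1 - a_hat)
                     + 1.0 / (n2 - m1 + a_hat))
        stat += (t.a - a_hat) ** 2 / var
    return stat


# ---------------------------------------------------------------------------
# Hardy-Weinberg
# ---------------------------------------------------------------------------

def hwe_exact(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact Hardy-Weinberg test p-value (two-sided, by probability ordering).

    Sums, over all heterozygote counts with the observed parity and fixed
    allele counts, the conditional probabilities no larger than the observed
    configuration's.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("negative genotype count")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("empty sample")
    rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    # conditional probabilities over het counts of the observed parity; the
    # recurrence is anchored at the modal count to avoid over/underflow
    mode = int(round(rare * (2 * n - rare) / (2.0 * n)))
    if mode % 2 != rare % 2:
        mode += 1
    mode = min(mode, rare)
    probs: dict[int, float] = {mode: 1.0}
    h = mode
    while h >= 2:
        hom_r = (rare - h) // 2
        hom_c = n - hom_r - h
        probs[h - 2] = probs[h] * h * (h - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
        h -= 2
    h = mode
    while h + 2 <= rare:
        hom_r = (rare - h) // 2
        hom_c = n - hom_r - h
        probs[h + 2] = probs[h] * 4.0 * hom_r * hom_c / ((h + 2.0) * (h + 1.0))
        h += 2
    total = sum(probs.values())
    p_obs = probs[n_het] / total
    p = sum(v for v in probs.values() if v / total <= p_obs * (1.0 + 1e-10)) / total
    return float(min(1.0, p))


def hwe_chi2(n_hom_ref: int, n_het: int, n_hom_alt: int) -> tuple[float, float]:
    """One-df chi-square Hardy-Weinberg test (statistic, p)."""
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("empty sample")
    p_ref = (2 * n_hom_ref + n_het) / (2.0 * n)
    expected = n * np.array([p_ref**2, 2 * p_ref * (1 - p_ref), (1 - p_ref) ** 2])
    observed = np.array([n_hom_ref, n_het, n_hom_alt], dtype=float)
    if p_ref in (0.0, 1.0):  # monomorphic: perfect fit by construction
        return 0.0, 1.0
    stat = float(((observed - expected) ** 2 / expected).sum())
    return stat, float(scipy.stats.chi2.sf(stat, 1))
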
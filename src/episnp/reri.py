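"""Relative excess risk due to interaction (RERI) on two-locus genotypes.

RERI = OR11 - OR10 - OR01 + 1, where OR11, OR10, OR01 are the odds ratios
of the doubly exposed and each singly exposed genotype against a common
doubly-unexposed reference cell.  RERI = 0 under additivity of excess
risks; in a rare-disease case-control design the odds ratios stand in for
relative risks.

Exposure contrasts for a biallelic SNP pair:

* H1 -- one copy of the risk allele at each locus (reference: doubly
  non-risk homozygote);
* H2 -- two copies at each locus (same reference);
* H3 -- one additional copy given one copy already carried (reference:
  the double heterozygote).

Confidence intervals come from the MOVER (method of variance estimates
recovery) combination of the three asymmetric OR intervals; because the
three 2x2 tables share the reference cell, their log-OR estimates are
positively correlated, and the correlated MOVER form is the default.
Significance is assessed by case/control-stratified bootstrap resampling.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import io
from .exceptions import DegenerateTableError, MissingCovariateError
from .single_locus import _covariate_columns
from .stats import OrEstimate, TwoByTwo, logistic_fit, or_woolf

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExposureContrast:
    """Four joint-dosage cells defining one RERI scenario."""

    label: str
    reference: tuple[int, int]
    exposed_a: tuple[int, int]
    exposed_b: tuple[int, int]
    exposed_both: tuple[int, int]

    def cells(self) -> tuple[tuple[int, int], ...]:
        return (self.reference, self.exposed_a, self.exposed_b, self.exposed_both)

    def __post_init__(self) -> None:
        if len(set(self.cells())) != 4:
            raise ValueError("contrast cells must be distinct")


H1 = ExposureContrast("H1", (0, 0), (1, 0), (0, 1), (1, 1))
H2 = ExposureContrast("H2", (0, 0), (2, 0), (0, 2), (2, 2))
H3 = ExposureContrast("H3", (1, 1), (2, 1), (1, 2), (2, 2))
STANDARD_CONTRASTS: dict[str, ExposureContrast] = {"H1": H1, "H2": H2, "H3": H3}


@dataclass
class ReriResult:
    reri: float
    or11: OrEstimate
    or10: OrEstimate
    or01: OrEstimate
    ci_low: float
    ci_high: float
    contrast: ExposureContrast
    adjusted: bool = False
    covariates: tuple[str, ...] = ()
    p_boot: float | None = None
    reps: int | None = None
    seed: int | None = None
    n_degenerate: int = 0
    unstable: bool = False


def reri_point(or11: float, or10: float, or01: float) -> float:
    """RERI = OR11 - OR10 - OR01 + 1."""
    if min(or11, or10, or01) <= 0:
        raise ValueError("odds ratios must be positive")
    return or11 - or10 - or01 + 1.0


def mover_ci(
    est11: OrEstimate,
    est10: OrEstimate,
    est01: OrEstimate,
    r12: float = 0.0,
    r13: float = 0.0,
    r23: float = 0.0,
) -> tuple[float, float]:
    """MOVER 95% limits for theta1 - theta2 - theta3 + 1.

    r12/r13 are the correlations of the doubly-exposed log-OR with each
    singly-exposed log-OR, r23 between the two singly-exposed log-ORs;
    all zero recovers the independent MOVER form.
    """
    for r in (r12, r13, r23):
        if not -1.0 <= r <= 1.0:
            raise ValueError("correlations must lie in [-1, 1]")
    t1, l1, u1 = est11.or_value, est11.ci_low, est11.ci_high
    t2, l2, u2 = est10.or_value, est10.ci_low, est10.ci_high
    t3, l3, u3 = est01.or_value, est01.ci_low, est01.ci_high
    point = reri_point(t1, t2, t3)
    low = point - math.sqrt(
        (t1 - l1) ** 2 + (u2 - t2) ** 2 + (u3 - t3) ** 2
        - 2 * r12 * (t1 - l1) * (u2 - t2)
        - 2 * r13 * (t1 - l1) * (u3 - t3)
        + 2 * r23 * (u2 - t2) * (u3 - t3)
    )
    high = point + math.sqrt(
        (u1 - t1) ** 2 + (t2 - l2) ** 2 + (t3 - l3) ** 2
        - 2 * r12 * (u1 - t1) * (t2 - l2)
        - 2 * r13 * (u1 - t1) * (t3 - l3)
        + 2 * r23 * (t2 - l2) * (t3 - l3)
    )
    return low, high


def _contrast_counts(table: io.TwoLocusTable, contrast: ExposureContrast) -> np.ndarray:
    """(4, 2) array of (cases, controls) for reference, A-only, B-only, both."""
    return np.array([table.cell(*g) for g in contrast.cells()], dtype=float)


def reri_from_counts(
    table: io.TwoLocusTable,
    contrast: ExposureContrast,
    correlated: bool = True,
) -> ReriResult:
    """Unadjusted RERI from a two-locus count table.

    Component ORs are cross-products against the contrast's reference cell;
    correlations between the shared-reference log-ORs are derived from the
    multinomial structure: cov(log OR_i, log OR_j) = 1/c + 1/d with c, d
    the reference cell's case and control counts.
    """
    counts = _contrast_counts(table, contrast)
    if (counts == 0).any():
        raise DegenerateTableError(
            f"empty cell in contrast {contrast.label}: counts {counts.tolist()}"
        )
    ref_c, ref_n = counts[0]
    ests = {}
    for key, (nc, nn) in zip(("both", "a", "b"), counts[[3, 1, 2]]):
        ests[key] = or_woolf(TwoByTwo(int(nc), int(nn), int(ref_c), int(ref_n)))
    e11, e10, e01 = ests["both"], ests["a"], ests["b"]
    if correlated:
        shared = 1.0 / ref_c + 1.0 / ref_n
        r12 = shared / (e11.se_log_or * e10.se_log_or)
        r13 = shared / (e11.se_log_or * e01.se_log_or)
        r23 = shared / (e10.se_log_or * e01.se_log_or)
    else:
        r12 = r13 = r23 = 0.0
    low, high = mover_ci(e11, e10, e01, r12, r13, r23)
    return ReriResult(
        reri_point(e11.or_value, e10.or_value, e01.or_value),
        e11, e10, e01, low, high, contrast,
    )


def reri_model(
    cohort: io.Cohort,
    snp_a: str,
    snp_b: str,
    contrast: ExposureContrast,
    covariates: Sequence[str] = (),
    correlated: bool = True,
) -> ReriResult:
    """RERI from an indicator-coded logistic model, optionally adjusted.

    Restricted to subjects falling in the four contrast cells; status is
    regressed on indicators for the three exposed cells (+ covariates).
    Without covariates this reproduces :func:`reri_from_counts` exactly.
    """
    spec_a, spec_b = cohort.specs[snp_a], cohort.specs[snp_b]
    cells = contrast.cells()
    subjects, joint = [], []
    for s in cohort.subjects:
        da = io.dosage(s.calls.get(snp_a, io.GenotypeCall.missing()), spec_a)
        db = io.dosage(s.calls.get(snp_b, io.GenotypeCall.missing()), spec_b)
        if da is None or db is None or (da, db) not in cells:
            continue
        subjects.append(s)
        joint.append((da, db))
    exposed = (contrast.exposed_both, contrast.exposed_a, contrast.exposed_b)
    indicators = np.array([[1.0 if c == g else 0.0 for g in exposed] for c in joint])
    y = np.array([1.0 if s.is_case else 0.0 for s in subjects])
    cov_x, cov_names = _covariate_columns(subjects, covariates)
    X = np.column_stack([np.ones_like(y), indicators, cov_x])
    names = ["intercept", "both", "a_only", "b_only"] + cov_names
    fit = logistic_fit(X, y, names=names)
    e11, e10, e01 = fit.term(1), fit.term(2), fit.term(3)
    if correlated:
        cov = fit.covariance[1:4, 1:4]
        sd = np.sqrt(np.diag(cov))
        corr = cov / np.outer(sd, sd)
        r12, r13, r23 = corr[0, 1], corr[0, 2], corr[1, 2]
    else:
        r12 = r13 = r23 = 0.0
    low, high = mover_ci(e11, e10, e01, r12, r13, r23)
    return ReriResult(
        reri_point(e11.or_value, e10.or_value, e01.or_value),
        e11, e10, e01, low, high, contrast,
        adjusted=bool(covariates), covariates=tuple(covariates),
    )


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BootstrapP:
    p: float
    reps: int
    n_valid: int
    n_degenerate: int
    unstable: bool


def _bootstrap_counts(
    table: io.TwoLocusTable,
    contrast: ExposureContrast,
    reps: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """Vectorised stratified bootstrap: multinomial resampling of the nine
    cells within cases and within controls (equivalent to resampling
    subjects with replacement, preserving n_cases and n_controls)."""
    n_case, n_ctrl = table.n_cases, table.n_controls
    p_case = table.cases.ravel() / n_case
    p_ctrl = table.controls.ravel() / n_ctrl
    case_draw = rng.multinomial(n_case, p_case, size=reps).reshape(reps, 3, 3)
    ctrl_draw = rng.multinomial(n_ctrl, p_ctrl, size=reps).reshape(reps, 3, 3)
    cells = contrast.cells()
    cc = np.stack([case_draw[:, g[0], g[1]] for g in cells], axis=1).astype(float)
    cn = np.stack([ctrl_draw[:, g[0], g[1]] for g in cells], axis=1).astype(float)
    valid = (cc > 0).all(axis=1) & (cn > 0).all(axis=1)
    ref_c, ref_n = cc[:, 0], cn[:, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        or_both = cc[:, 3] * ref_n / (cn[:, 3] * ref_c)
        or_a = cc[:, 1] * ref_n / (cn[:, 1] * ref_c)
        or_b = cc[:, 2] * ref_n / (cn[:, 2] * ref_c)
        reri = or_both - or_a - or_b + 1.0
    return reri[valid], int(reps - valid.sum())


def bootstrap_p(
    data: io.TwoLocusTable | io.Cohort,
    contrast: ExposureContrast,
    reps: int = 10_000,
    seed: int | None = None,
    covariates: Sequence[str] = (),
    snp_a: str | None = None,
    snp_b: str | None = None,
) -> BootstrapP:
    """Two-sided percentile bootstrap p-value for RERI = 0.

    Resampling is stratified by case/control status.  The p-value is
    2 * min(frac(RERI <= 0), frac(RERI >= 0)) over non-degenerate
    replicates, floored at 1/reps and capped at 1; replicates with an
    empty contrast cell are skipped and counted.  Deterministic per seed.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if seed is None:
        raise ValueError("a seed is required for reproducible bootstrap p-values")
    rng = np.random.default_rng(seed)

    if covariates:
        if not isinstance(data, io.Cohort):
            raise MissingCovariateError("adjusted bootstrap needs subject-level data")
        reris = []
        n_degenerate = 0
        subjects = data.subjects
        n = len(subjects)
        is_case = np.array([s.is_case for s in subjects])
        case_idx = np.flatnonzero(is_case)
        ctrl_idx = np.flatnonzero(~is_case)
        for _ in range(reps):
            idx = np.concatenate([
                rng.choice(case_idx, size=case_idx.size, replace=True),
                rng.choice(ctrl_idx, size=ctrl_idx.size, replace=True),
            ])
            resampled = io.Cohort(
                [_clone_subject(subjects[i], k) for k, i in enumerate(idx)],
                data.specs, label=data.label,
            )
            try:
                res = reri_model(resampled, snp_a, snp_b, contrast, covariates)
            except Exception:  # degenerate replicate
                n_degenerate += 1
                continue
            reris.append(res.reri)
        reri_arr = np.array(reris)
    else:
        table = data if isinstance(data, io.TwoLocusTable) else io.crosstab_pair(data, snp_a, snp_b)
        reri_arr, n_degenerate = _bootstrap_counts(table, contrast, reps, rng)

    n_valid = reri_arr.size
    if n_valid == 0:
        raise DegenerateTableError("all bootstrap replicates degenerate")
    frac_le = float(np.mean(reri_arr <= 0.0))
    frac_ge = float(np.mean(reri_arr >= 0.0))
    p = min(1.0, max(2.0 * min(frac_le, frac_ge), 1.0 / reps))
    unstable = n_degenerate > 0.10 * reps
    if unstable:
        logger.warning("bootstrap unstable: %d/%d degenerate replicates", n_degenerate, reps)
    return BootstrapP(p, reps, n_valid, n_degenerate, unstable)


def _clone_subject(s: io.Subject, k: int) -> io.Subject:
    return io.Subject(f"b{k}", s.sex, s.age, s.status, s.calls)
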
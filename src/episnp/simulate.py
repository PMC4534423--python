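"""Synthetic case-control cohorts with known two-locus interaction structure.

The generator draws a retrospective (status-conditional) sample of two
biallelic SNPs in linkage equilibrium, each with Hardy-Weinberg genotype
frequencies in the source population, pushed through a configurable 3x3
penetrance matrix:

* ``risk_additive``   -- P(D | gA, gB) = b + gA*eA + gB*eB + gA*gB*eAB
* ``odds_multiplicative`` -- logit P = logit(b) + gA*bA + gB*bB + gA*gB*g
* ``custom``          -- an explicit 3x3 matrix of probabilities

Sampling is exact for a case-control design: genotype (and covariate)
distributions conditional on status follow from Bayes' rule, and exactly
``n_cases`` cases and ``n_controls`` controls are drawn.  Sex and age are
independent of genotype; their optional log-odds effects on disease enter
the penetrance and are integrated over a discretised age grid for the
Bayes step.

Alongside each parameter set the module computes the generating model's
exact population quantities (:class:`TrueValues`): genotype frequencies,
odds ratios per genotype against the doubly non-risk reference, the true
RERI for the H1/H2/H3 contrasts, and the true multiplicative
additive-by-additive interaction OR -- the oracles for parameter-recovery
and calibration tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.special
import scipy.stats

from . import io, reri as reri_mod
from .exceptions import ParameterError
from .interaction import CodingScheme, interaction_test5, interaction_test6
from .io import Cohort, GenotypeCall, SnpSpec, Subject, TwoLocusTable
from .two_locus import genotype_or_profile

_AGE_GRID_POINTS = 81  # discretisation of the age distribution for exact Bayes sampling

DEFAULT_SPEC_A = SnpSpec("snpA", "G", "A")
DEFAULT_SPEC_B = SnpSpec("snpB", "C", "T")


@dataclass
class SimParams:
    """Generating-model parameters.

    Defaults emulate the study conditions the analyses are designed for:
    2,020 cases / 5,315 controls, risk-allele frequencies 0.32 and 0.50,
    a baseline disease risk of 0.8% (typical of atrial fibrillation), and
    per-allele odds ratios 1.30 and 1.57 with no interaction.
    """

    freq_a: float = 0.32  # population risk-allele frequency, SNP A
    freq_b: float = 0.50
    mode: str = "odds_multiplicative"  # risk_additive | odds_multiplicative | custom
    baseline: float = 0.008  # P(D) in the doubly non-risk reference genotype
    effect_a: float = math.log(1.30)  # excess risk (risk_additive) or log-odds per allele
    effect_b: float = math.log(1.57)
    interaction: float = 0.0  # excess-risk or log-odds interaction term
    penetrance: np.ndarray | None = None  # custom 3x3 matrix, overrides mode
    n_cases: int = 2020
    n_controls: int = 5315
    female_prop: float = 0.4
    age_mean: float = 60.0
    age_sd: float = 12.0
    sex_effect: float = 0.0  # log-odds shift for females
    age_effect: float = 0.0  # log-odds per year (centred at age_mean)
    spec_a: SnpSpec = field(default_factory=lambda: DEFAULT_SPEC_A)
    spec_b: SnpSpec = field(default_factory=lambda: DEFAULT_SPEC_B)

    def __post_init__(self) -> None:
        for name, f in (("freq_a", self.freq_a), ("freq_b", self.freq_b)):
            if not 0.0 < f < 1.0:
                raise ParameterError(f"{name} must lie in (0, 1)")
        if not 0.0 < self.baseline < 1.0:
            raise ParameterError("baseline risk must lie in (0, 1)")
        if self.mode not in ("risk_additive", "odds_multiplicative", "custom"):
            raise ParameterError(f"unknown interaction mode {self.mode!r}")
        if self.mode == "custom" and self.penetrance is None:
            raise ParameterError("custom mode requires a penetrance matrix")
        if not 0.0 <= self.female_prop <= 1.0:
            raise ParameterError("female_prop must lie in [0, 1]")
        if min(self.n_cases, self.n_controls) < 0:
            raise ParameterError("sample sizes must be non-negative")


@dataclass
class TrueValues:
    """Exact population quantities implied by a penetrance matrix."""

    genotype_freqs: np.ndarray  # (3, 3), HWE x linkage equilibrium
    penetrance: np.ndarray  # (3, 3)
    or_matrix: np.ndarray  # odds ratio of each genotype vs (0, 0)
    rr_matrix: np.ndarray  # relative risk of each genotype vs (0, 0)
    reri: dict[str, float]  # true RERI per H1/H2/H3 (odds-ratio based)
    interaction_or: float  # multiplicative A-by-A interaction OR (risk orientation)


def _hwe_freqs(freq: float) -> np.ndarray:
    q = 1.0 - freq
    return np.array([q * q, 2 * q * freq, freq * freq])


def build_penetrance(params: SimParams) -> tuple[np.ndarray, TrueValues]:
    """Penetrance matrix and its implied exact quantities.

    Raises :class:`ParameterError` (never clips silently) if any cell of a
    ``risk_additive`` matrix would fall outside (0, 1).
    """
    g = np.arange(3, dtype=float)
    ga, gb = np.meshgrid(g, g, indexing="ij")
    if params.penetrance is not None or params.mode == "custom":
        pen = np.asarray(params.penetrance, dtype=float)
        if pen.shape != (3, 3):
            raise ParameterError("custom penetrance matrix must be 3x3")
    elif params.mode == "risk_additive":
        pen = params.baseline + ga * params.effect_a + gb * params.effect_b \
            + ga * gb * params.interaction
    else:  # odds_multiplicative
        logit = scipy.special.logit(params.baseline) + ga * params.effect_a \
            + gb * params.effect_b + ga * gb * params.interaction
        pen = scipy.special.expit(logit)
    if (pen <= 0.0).any() or (pen >= 1.0).any():
        raise ParameterError("penetrance outside (0, 1); adjust effects or baseline")

    freqs = np.outer(_hwe_freqs(params.freq_a), _hwe_freqs(params.freq_b))
    odds = pen / (1.0 - pen)
    or_matrix = odds / odds[0, 0]
    rr_matrix = pen / pen[0, 0]
    reri_true = {}
    for label, c in reri_mod.STANDARD_CONTRASTS.items():
        ref = or_matrix[c.reference]
        reri_true[label] = (
            or_matrix[c.exposed_both] / ref
            - or_matrix[c.exposed_a] / ref
            - or_matrix[c.exposed_b] / ref
            + 1.0
        )
    interaction_or = float(odds[1, 1] * odds[0, 0] / (odds[1, 0] * odds[0, 1]))
    return pen, TrueValues(freqs, pen, or_matrix, rr_matrix, reri_true, interaction_or)


def _age_grid(params: SimParams) -> tuple[np.ndarray, np.ndarray]:
    """Discretised age distribution (values, probabilities)."""
    lo, hi = params.age_mean - 4 * params.age_sd, params.age_mean + 4 * params.age_sd
    ages = np.linspace(max(lo, 0.0), hi, _AGE_GRID_POINTS)
    w = scipy.stats.norm.pdf(ages, params.age_mean, params.age_sd)
    return ages, w / w.sum()


def _marginal_penetrance(params: SimParams, pen: np.ndarray) -> np.ndarray:
    """Penetrance integrated over the covariate distribution."""
    if params.sex_effect == 0.0 and params.age_effect == 0.0:
        return pen
    ages, w_age = _age_grid(params)
    shift = (
        params.sex_effect * np.array([0.0, 1.0])[None, :]
        + params.age_effect * (ages - params.age_mean)[:, None]
    )  # (age, sex)
    w = w_age[:, None] * np.array([1.0 - params.female_prop, params.female_prop])[None, :]
    logit_g = scipy.special.logit(pen)
    out = np.zeros_like(pen)
    for i in range(3):
        for j in range(3):
            out[i, j] = float(np.sum(w * scipy.special.expit(logit_g[i, j] + shift)))
    return out


def simulate_table(params: SimParams, seed: int) -> TwoLocusTable:
    """Draw a two-locus count table directly (fast path, no Subject objects)."""
    pen, _ = build_penetrance(params)
    pen_m = _marginal_penetrance(params, pen)
    freqs = np.outer(_hwe_freqs(params.freq_a), _hwe_freqs(params.freq_b))
    p_case = (freqs * pen_m).ravel()
    p_case /= p_case.sum()
    p_ctrl = (freqs * (1.0 - pen_m)).ravel()
    p_ctrl /= p_ctrl.sum()
    rng = np.random.default_rng(seed)
    counts = np.zeros((3, 3, 2), dtype=int)
    counts[:, :, 0] = rng.multinomial(params.n_cases, p_case).reshape(3, 3)
    counts[:, :, 1] = rng.multinomial(params.n_controls, p_ctrl).reshape(3, 3)
    return TwoLocusTable(counts, params.spec_a, params.spec_b)


def simulate_cohort(params: SimParams, seed: int) -> Cohort:
    """Draw a subject-level cohort, deterministic per seed.

    Joint sampling of (genotype pair, sex, age) conditional on status over
    a discretised age grid, so the generated data follow the stated model
    exactly (within the discretisation).
    """
    pen, _ = build_penetrance(params)
    freqs = np.outer(_hwe_freqs(params.freq_a), _hwe_freqs(params.freq_b))
    ages, w_age = _age_grid(params)
    p_sex = np.array([1.0 - params.female_prop, params.female_prop])
    logit_g = scipy.special.logit(pen)
    shift = (
        params.sex_effect * np.array([0.0, 1.0])[None, :]
        + params.age_effect * (ages - params.age_mean)[:, None]
    )  # (age, sex)
    pen_gxs = scipy.special.expit(logit_g[:, :, None, None] + shift.T[None, None, :, :])
    # joint weights over (gA, gB, sex, age)
    base = freqs[:, :, None, None] * p_sex[None, None, :, None] * w_age[None, None, None, :]
    w_case = (base * pen_gxs).ravel()
    w_ctrl = (base * (1.0 - pen_gxs)).ravel()
    rng = np.random.default_rng(seed)
    shape = (3, 3, 2, ages.size)

    def draw(n: int, weights: np.ndarray, status: int, prefix: str) -> list[Subject]:
        idx = rng.choice(weights.size, size=n, p=weights / weights.sum())
        ga, gb, sex_i, age_i = np.unravel_index(idx, shape)
        out = []
        for k in range(n):
            calls = {
                params.spec_a.name: GenotypeCall.parse(
                    params.spec_a.genotype_label(int(ga[k])), params.spec_a),
                params.spec_b.name: GenotypeCall.parse(
                    params.spec_b.genotype_label(int(gb[k])), params.spec_b),
            }
            out.append(Subject(
                f"{prefix}{k + 1:06d}", int(sex_i[k]) + 1,
                float(round(ages[age_i[k]], 1)), status, calls,
            ))
        return out

    subjects = draw(params.n_cases, w_case, 2, "case") + \
        draw(params.n_controls, w_ctrl, 1, "ctrl")
    return Cohort(subjects, {params.spec_a.name: params.spec_a,
                             params.spec_b.name: params.spec_b},
                  label="synthetic")


def recovery_suite(
    params: SimParams,
    n_reps: int,
    seed: int,
    n_boot: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Estimator bias / coverage / rejection summary over simulated replicates.

    Per replicate: simulate a count table, run the genotype-OR profile,
    RERI (H1/H2/H3 with MOVER CIs, optional bootstrap p at *n_boot* reps)
    and both interaction tests (risk-allele orientation, so estimates map
    directly onto the generating parameters), and compare against the
    generating model's :class:`TrueValues`.
    """
    if n_reps < 50:
        raise ParameterError("recovery_suite needs at least 50 replicates")
    _, true = build_penetrance(params)
    rng = np.random.default_rng(seed)
    coding = CodingScheme("risk")

    reri_est = {k: [] for k in reri_mod.STANDARD_CONTRASTS}
    reri_cover = {k: [] for k in reri_mod.STANDARD_CONTRASTS}
    reri_reject = {k: [] for k in reri_mod.STANDARD_CONTRASTS}
    boot_reject = {k: [] for k in reri_mod.STANDARD_CONTRASTS}
    axa_est, axa_cover, axa_reject = [], [], []
    or22_est = []
    n_degenerate = 0

    for _ in range(n_reps):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        table = simulate_table(params, rep_seed)
        try:
            profile = genotype_or_profile(table)
            or22_est.append(profile.estimate((2, 2)).or_value)
            for label, contrast in reri_mod.STANDARD_CONTRASTS.items():
                res = reri_mod.reri_from_counts(table, contrast)
                t = true.reri[label]
                reri_est[label].append(res.reri)
                reri_cover[label].append(res.ci_low <= t <= res.ci_high)
                reri_reject[label].append(not res.ci_low <= 0.0 <= res.ci_high)
                if n_boot:
                    bp = reri_mod.bootstrap_p(table, contrast, reps=n_boot,
                                              seed=rep_seed + 1)
                    boot_reject[label].append(bp.p < alpha)
            f5 = interaction_test5(table, coding=coding)
            est = f5.terms["AxA"].estimate
            axa_est.append(est.or_value)
            axa_cover.append(est.ci_low <= true.interaction_or <= est.ci_high)
            axa_reject.append(f5.terms["AxA"].p < alpha)
        except Exception:
            n_degenerate += 1
            continue

    def summary(label):
        est = np.array(reri_est[label])
        out = {
            "mean": float(est.mean()),
            "bias": float(est.mean() - true.reri[label]),
            "ci_coverage": float(np.mean(reri_cover[label])),
            "ci_rejection": float(np.mean(reri_reject[label])),
        }
        if n_boot:
            out["bootstrap_rejection"] = float(np.mean(boot_reject[label]))
        return out

    return {
        "n_reps": n_reps,
        "n_degenerate": n_degenerate,
        "true": {"reri": dict(true.reri), "interaction_or": true.interaction_or,
                 "or22": float(true.or_matrix[2, 2])},
        "reri": {label: summary(label) for label in reri_mod.STANDARD_CONTRASTS},
        "test5_axa": {
            "mean_or": float(np.mean(axa_est)),
            "ci_coverage": float(np.mean(axa_cover)),
            "rejection": float(np.mean(axa_reject)),
        },
        "profile_or22": {
            "mean": float(np.mean(or22_est)),
            "relative_bias": float(np.mean(or22_est) / true.or_matrix[2, 2] - 1.0),
        },
    }
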
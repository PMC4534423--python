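"""End-to-end orchestration of the two-locus interaction analysis.

One :class:`RunConfig` describes the inputs (subject tables or aggregated
counts, per population), the SNP pair(s), covariates, bootstrap settings
and the output directory; :func:`run_pipeline` produces, per population
and for the combined population, the Hardy-Weinberg gate, single-locus
association tables, the genotype odds-ratio profile with synergy summary
and Breslow-Day comparisons, the H1/H2/H3 RERI table, and both genotypic
interaction tests, plus a JSON manifest (seed, versions, input checksums).

A failure in one analysis is recorded in the bundle's ``errors`` and does
not abort the remaining analyses.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__, io, reri as reri_mod
from .interaction import CodingScheme, interaction_test5, interaction_test6
from .single_locus import allelic_association, hwe_gate, model_association
from .two_locus import compare_genotype_ors, genotype_or_profile, synergy_summary

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one reproducible run needs."""

    inputs: dict[str, str]  # population label -> path
    specs: list[io.SnpSpec]
    pairs: list[tuple[str, str]]
    input_kind: str = "subjects"  # subjects | counts | ped
    reference: tuple[int, int] = (0, 0)
    covariates: tuple[str, ...] = ()
    contrasts: tuple[str, ...] = ("H1", "H2", "H3")
    reps: int = 10_000
    seed: int | None = None
    outdir: str | None = None
    combine: bool = True
    coding: CodingScheme = field(default_factory=CodingScheme)

    def __post_init__(self) -> None:
        names = {s.name for s in self.specs}
        for a, b in self.pairs:
            if a not in names or b not in names:
                raise ValueError(f"pair ({a}, {b}) has no matching SNP spec")
        if self.reps and self.seed is None:
            raise ValueError("a seed is required when bootstrap is enabled")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        specs = [io.SnpSpec(d["name"], d["allele_nonrisk"], d["allele_risk"])
                 for d in raw["specs"]]
        return cls(
            inputs=dict(raw["inputs"]),
            specs=specs,
            pairs=[tuple(p) for p in raw["pairs"]],
            input_kind=raw.get("input_kind", "subjects"),
            reference=tuple(raw.get("reference", (0, 0))),
            covariates=tuple(raw.get("covariates", ())),
            contrasts=tuple(raw.get("contrasts", ("H1", "H2", "H3"))),
            reps=int(raw.get("reps", 10_000)),
            seed=raw.get("seed"),
            outdir=raw.get("outdir"),
            combine=bool(raw.get("combine", True)),
            coding=CodingScheme(raw.get("coding_orientation", "minor")),
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_inputs(config: RunConfig):
    """Returns {population: cohort-or-{pair: table}} keyed by label."""
    spec_map = {s.name: s for s in config.specs}
    loaded: dict[str, object] = {}
    for label, path in config.inputs.items():
        if config.input_kind == "counts":
            tables = {}
            for a, b in config.pairs:
                tables[(a, b)] = io.read_counts(path, spec_map[a], spec_map[b])
            loaded[label] = tables
        else:
            dialect = "ped" if config.input_kind == "ped" else "table"
            loaded[label] = io.read_cohort(path, config.specs, dialect=dialect, label=label)
    if config.combine and len(loaded) > 1:
        first = next(iter(loaded.values()))
        if isinstance(first, io.Cohort):
            subjects = []
            for pop, cohort in loaded.items():
                for s in cohort.subjects:
                    subjects.append(io.Subject(f"{pop}:{s.id}", s.sex, s.age, s.status, s.calls))
            loaded["combined"] = io.Cohort(subjects, spec_map, label="combined")
        else:
            combined = {}
            for pair in first:
                total = None
                for tables in loaded.values():
                    total = tables[pair] if total is None else total + tables[pair]
                combined[pair] = total
            loaded["combined"] = combined
    return loaded


def _profile_frame(profile, synergy) -> tuple[pd.DataFrame, dict]:
    df = profile.rows.copy()
    df["or_formatted"] = [
        "1.00 (ref)" if np.isnan(lo) else io.format_or(o, lo, hi)
        for o, lo, hi in zip(df["or"], df["ci_low"], df["ci_high"])
    ]
    syn = {
        "or_both": synergy.or_both,
        "or_a_only": synergy.or_a_only,
        "or_b_only": synergy.or_b_only,
        "sum_single": synergy.sum_single,
        "exceeds_sum": synergy.exceeds_sum,
        "product_single": synergy.product_single,
        "exceeds_product": synergy.exceeds_product,
        "breslow_day_p_vs_a_only": synergy.bd_p_vs_a_only,
        "breslow_day_p_vs_b_only": synergy.bd_p_vs_b_only,
    }
    return df, syn


def run_pipeline(config: RunConfig) -> dict:
    """Run every analysis stage for every population and SNP pair.

    Returns a nested bundle ``{population: {stage: result}}`` plus a
    ``manifest``; writes TSV/JSON outputs when ``config.outdir`` is set.
    """
    loaded = _load_inputs(config)
    spec_map = {s.name: s for s in config.specs}
    bundle: dict = {"errors": [], "populations": {}}
    rng = np.random.default_rng(config.seed)

    for label, data in loaded.items():
        pop: dict = {}
        subject_level = isinstance(data, io.Cohort)

        def attempt(stage: str, fn):
            try:
                return fn()
            except Exception as exc:  # stage isolation
                msg = f"{label}/{stage}: {type(exc).__name__}: {exc}"
                bundle["errors"].append(msg)
                logger.warning(msg)
                return None

        # --- single-locus + HWE gate -------------------------------------
        hwe_rows, assoc_rows = [], []
        for a, b in config.pairs:
            for which, snp in (("a", a), ("b", b)):
                counts = (
                    io.crosstab_single(data, snp) if subject_level
                    else data[(a, b)].marginal(which)
                )
                gate = attempt(f"hwe:{snp}", lambda c=counts: hwe_gate(c))
                if gate:
                    hwe_rows.append({"snp": snp, "hwe_p": gate.p, "passed": gate.passed})
                res = attempt(f"allelic:{snp}", lambda c=counts: allelic_association(c))
                if res:
                    assoc_rows.append({
                        "snp": snp, "test": res.test, "or": res.estimate.or_value,
                        "ci_low": res.estimate.ci_low, "ci_high": res.estimate.ci_high,
                        "p": res.p,
                    })
                for model in ("additive", "dominant", "recessive"):
                    res = attempt(
                        f"{model}:{snp}",
                        lambda c=counts, m=model: model_association(c, m),
                    )
                    if res:
                        assoc_rows.append({
                            "snp": snp, "test": res.test, "or": res.estimate.or_value,
                            "ci_low": res.estimate.ci_low, "ci_high": res.estimate.ci_high,
                            "p": res.p,
                        })
        pop["hwe"] = pd.DataFrame(hwe_rows).drop_duplicates(subset="snp") if hwe_rows else pd.DataFrame()
        pop["association"] = pd.DataFrame(assoc_rows).drop_duplicates(subset=["snp", "test"]) \
            if assoc_rows else pd.DataFrame()

        # --- per pair: profile, RERI, interaction ------------------------
        for a, b in config.pairs:
            key = f"{a}x{b}"
            table = data[(a, b)] if not subject_level else io.crosstab_pair(data, a, b)
            cohort = data if subject_level else None
            covariates = config.covariates if subject_level else ()
            if config.covariates and not subject_level:
                logger.info("%s/%s: counts-only input, adjusted analyses skipped", label, key)

            def profile_stage():
                prof = genotype_or_profile(
                    table, config.reference,
                    cohort=cohort if covariates else None, covariates=covariates,
                )
                syn = synergy_summary(prof, use_adjusted=False)
                return _profile_frame(prof, syn)

            out = attempt(f"profile:{key}", profile_stage)
            if out:
                pop[f"profile:{key}"], pop[f"synergy:{key}"] = out

            def reri_stage():
                rows = []
                for cname in config.contrasts:
                    contrast = reri_mod.STANDARD_CONTRASTS[cname]
                    res = reri_mod.reri_from_counts(table, contrast)
                    boot = reri_mod.bootstrap_p(
                        table, contrast, reps=config.reps,
                        seed=int(rng.integers(0, 2**31 - 1)),
                    ) if config.reps else None
                    row = {
                        "contrast": cname, "reri": res.reri,
                        "ci_low": res.ci_low, "ci_high": res.ci_high,
                        "p_boot": boot.p if boot else np.nan,
                    }
                    if covariates:
                        adj = reri_mod.reri_model(cohort, a, b, contrast, covariates)
                        row.update({"reri_adj": adj.reri, "adj_ci_low": adj.ci_low,
                                    "adj_ci_high": adj.ci_high})
                    rows.append(row)
                return pd.DataFrame(rows)

            out = attempt(f"reri:{key}", reri_stage)
            if out is not None:
                pop[f"reri:{key}"] = out

            def interaction_stage():
                rows = []
                for test_name, fn in (("test6", interaction_test6), ("test5", interaction_test5)):
                    fit = fn(table, coding=config.coding)
                    for term, tr in fit.terms.items():
                        rows.append({
                            "test": test_name, "term": term,
                            "or": tr.estimate.or_value, "ci_low": tr.estimate.ci_low,
                            "ci_high": tr.estimate.ci_high, "p": tr.p,
                            "global_p": fit.global_p,
                        })
                    if covariates:
                        fit_adj = fn(cohort, coding=config.coding,
                                     covariates=covariates, snp_a=a, snp_b=b)
                        for term, tr in fit_adj.terms.items():
                            rows.append({
                                "test": f"{test_name}_adj", "term": term,
                                "or": tr.estimate.or_value, "ci_low": tr.estimate.ci_low,
                                "ci_high": tr.estimate.ci_high, "p": tr.p,
                                "global_p": fit_adj.global_p,
                            })
                return pd.DataFrame(rows)

            out = attempt(f"interaction:{key}", interaction_stage)
            if out is not None:
                pop[f"interaction:{key}"] = out

            def bd_stage():
                # doubly risk-homozygous vs each single-risk homozygote
                rows = []
                for other, name in (((2, 0), "a_only"), ((0, 2), "b_only")):
                    stat, p = compare_genotype_ors(table, (2, 2), other, config.reference)
                    rows.append({"comparison": f"both_vs_{name}", "statistic": stat, "p": p})
                return pd.DataFrame(rows)

            out = attempt(f"breslow_day:{key}", bd_stage)
            if out is not None:
                pop[f"breslow_day:{key}"] = out

        bundle["populations"][label] = pop

    bundle["manifest"] = {
        "package_version": __version__,
        "seed": config.seed,
        "reps": config.reps,
        "covariates": list(config.covariates),
        "coding_orientation": config.coding.orientation,
        "inputs": {
            label: {"path": str(p), "sha256": _sha256(Path(p))}
            for label, p in config.inputs.items()
        },
    }

    if config.outdir:
        _write_bundle(bundle, Path(config.outdir))
    return bundle


def _write_bundle(bundle: dict, outdir: Path) -> None:
    for label, pop in bundle["populations"].items():
        tables = {
            f"{label}.{name.replace(':', '.')}": obj
            for name, obj in pop.items() if isinstance(obj, pd.DataFrame)
        }
        extra = {
            name.replace(":", "."): obj
            for name, obj in pop.items() if not isinstance(obj, pd.DataFrame)
        }
        io.write_results(tables, outdir, summary={
            "population": label, "manifest": bundle["manifest"],
            "synergy": extra, "errors": bundle["errors"],
        })


def verify_against_reference(
    bundle: dict,
    expectations: Sequence[Mapping] | str | Path,
) -> pd.DataFrame:
    """Check a bundle against expected values.

    Each expectation is a mapping with keys ``population``, ``analysis``
    (stage key, e.g. ``profile:rs2106261xrs2200733``), ``where`` (column ->
    value selectors locating one row), ``column``, ``expected`` and ``tol``.
    Returns a frame with one pass/fail row per expectation; an empty
    expectation list passes trivially.
    """
    if isinstance(expectations, (str, Path)):
        expectations = yaml.safe_load(Path(expectations).read_text()) or []
    rows = []
    for exp in expectations:
        record = {k: exp.get(k) for k in ("population", "analysis", "column", "expected", "tol")}
        try:
            frame = bundle["populations"][exp["population"]][exp["analysis"]]
            mask = pd.Series(True, index=frame.index)
            for col, val in (exp.get("where") or {}).items():
                mask &= frame[col] == val
            sel = frame[mask]
            if len(sel) != 1:
                raise KeyError(f"selector matched {len(sel)} rows")
            actual = float(sel.iloc[0][exp["column"]])
            record["actual"] = actual
            record["passed"] = abs(actual - float(exp["expected"])) <= float(exp.get("tol", 0.005))
        except Exception as exc:
            record["actual"] = np.nan
            record["passed"] = False
            record["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(record)
    df = pd.DataFrame(rows)
    if df.empty:
        df = pd.DataFrame(columns=["population", "analysis", "column", "expected",
                                   "tol", "actual", "passed"])
    return df
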
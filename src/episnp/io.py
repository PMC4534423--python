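"""Subject-level genotype tables and the aggregate count structures.

The subject table layout is the one common in candidate-gene case-control
studies: one row per participant with an id, sex (1 = male, 2 = female),
age in years, affection status (1 = control, 2 = case) and one two-character
genotype string per SNP.  PLINK text PED/MAP files and pre-aggregated
nine-row two-locus count tables are accepted as alternative dialects.

All downstream statistics consume either a :class:`GenotypeCounts` (one SNP,
counts by risk-allele dosage and status) or a :class:`TwoLocusTable`
(3x3x2 counts over the joint dosages of a SNP pair).  Missing genotypes are
handled complete-case per analysis: a subject missing one SNP of a pair
still contributes to the other SNP's single-locus table.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    DuplicateSubjectError,
    InvalidAlleleError,
    InvalidCodingError,
)

logger = logging.getLogger(__name__)

#: Genotype cell contents treated as a missing call.
MISSING_TOKENS = frozenset(
    {"", "0", "00", "-", "--", "NN", "N", "NA", "N/A", "NAN", ".", "..", "./."}
)

_VALID_NUCLEOTIDES = frozenset("ACGT")

#: Row-major order of the nine two-locus dosage cells used throughout.
GENOTYPE_ORDER: tuple[tuple[int, int], ...] = (
    (0, 0), (0, 1), (0, 2),
    (1, 0), (1, 1), (1, 2),
    (2, 0), (2, 1), (2, 2),
)


@dataclass(frozen=True)
class SnpSpec:
    """A biallelic SNP with a designated risk and non-risk allele."""

    name: str
    allele_nonrisk: str
    allele_risk: str

    def __post_init__(self) -> None:
        for allele in (self.allele_nonrisk, self.allele_risk):
            if allele not in _VALID_NUCLEOTIDES:
                raise InvalidAlleleError(
                    f"{self.name}: allele {allele!r} is not an uppercase nucleotide"
                )
        if self.allele_nonrisk == self.allele_risk:
            raise InvalidAlleleError(f"{self.name}: risk and non-risk alleles coincide")

    @property
    def alleles(self) -> frozenset[str]:
        return frozenset((self.allele_nonrisk, self.allele_risk))

    def genotype_label(self, dosage: int) -> str:
        """Two-character genotype string for a risk-allele dosage, e.g. ``AG``.

        Heterozygotes are written with alleles in alphabetical order, matching
        the usual tabulation style (AG, CT, ...).
        """
        if dosage == 0:
            return self.allele_nonrisk * 2
        if dosage == 2:
            return self.allele_risk * 2
        return "".join(sorted((self.allele_nonrisk, self.allele_risk)))


@dataclass(frozen=True)
class GenotypeCall:
    """An unordered pair of alleles, or a missing call (``alleles is None``)."""

    alleles: tuple[str, str] | None

    @classmethod
    def missing(cls) -> "GenotypeCall":
        return cls(None)

    @classmethod
    def parse(cls, text: str, spec: SnpSpec) -> "GenotypeCall":
        """Parse a genotype cell; ``AG``/``GA``/``a/g``/``A|G`` are identical.

        Raises :class:`InvalidAlleleError` for characters outside the spec's
        two alleles; returns a missing call for recognised missing tokens.
        """
        cleaned = text.strip().upper().replace("/", "").replace("|", "").replace(" ", "")
        if cleaned in MISSING_TOKENS:
            return cls.missing()
        if len(cleaned) != 2:
            return cls.missing()
        for ch in cleaned:
            if ch not in spec.alleles:
                raise InvalidAlleleError(
                    f"{spec.name}: allele {ch!r} not in {{{spec.allele_nonrisk},{spec.allele_risk}}}"
                )
        pair = tuple(sorted(cleaned))
        return cls((pair[0], pair[1]))

    @property
    def is_missing(self) -> bool:
        return self.alleles is None

    def __str__(self) -> str:
        return "00" if self.alleles is None else "".join(self.alleles)


def dosage(call: GenotypeCall, spec: SnpSpec) -> int | None:
    """Number of risk alleles carried (0/1/2), or None for a missing call."""
    if call.is_missing:
        return None
    return sum(1 for a in call.alleles if a == spec.allele_risk)


@dataclass
class Subject:
    """One study participant."""

    id: str
    sex: int | None  # 1 = male, 2 = female
    age: float | None  # years
    status: int  # 1 = control, 2 = case
    calls: dict[str, GenotypeCall] = field(default_factory=dict)

    @property
    def is_case(self) -> bool:
        return self.status == 2


@dataclass
class Cohort:
    """An ordered collection of subjects plus the SNP specs they were typed on."""

    subjects: list[Subject]
    specs: dict[str, SnpSpec]
    label: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for s in self.subjects:
            if s.id in seen:
                raise DuplicateSubjectError(f"duplicate subject id {s.id!r}")
            seen.add(s.id)
            for snp in s.calls:
                if snp not in self.specs:
                    raise KeyError(f"genotype call for unknown SNP {snp!r}")

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def n_cases(self) -> int:
        return sum(1 for s in self.subjects if s.is_case)

    @property
    def n_controls(self) -> int:
        return len(self.subjects) - self.n_cases


@dataclass
class GenotypeCounts:
    """Case/control counts for one SNP, indexed by risk-allele dosage 0/1/2."""

    snp: str
    cases: np.ndarray  # shape (3,)
    controls: np.ndarray  # shape (3,)

    def __post_init__(self) -> None:
        self.cases = np.asarray(self.cases, dtype=int)
        self.controls = np.asarray(self.controls, dtype=int)
        if self.cases.shape != (3,) or self.controls.shape != (3,):
            raise ValueError("genotype counts must have one entry per dosage 0/1/2")
        if (self.cases < 0).any() or (self.controls < 0).any():
            raise ValueError("negative genotype count")

    @property
    def n_cases(self) -> int:
        return int(self.cases.sum())

    @property
    def n_controls(self) -> int:
        return int(self.controls.sum())

    def allele_counts(self) -> tuple[int, int, int, int]:
        """(case risk, case non-risk, control risk, control non-risk) allele counts."""
        cr = 2 * self.cases[2] + self.cases[1]
        cn = 2 * self.cases[0] + self.cases[1]
        tr = 2 * self.controls[2] + self.controls[1]
        tn = 2 * self.controls[0] + self.controls[1]
        return int(cr), int(cn), int(tr), int(tn)


@dataclass
class TwoLocusTable:
    """3x3x2 counts over joint risk-allele dosages of a SNP pair.

    ``counts[i, j, 0]`` holds cases and ``counts[i, j, 1]`` controls with
    dosage ``i`` at SNP A and ``j`` at SNP B.
    """

    counts: np.ndarray  # shape (3, 3, 2)
    spec_a: SnpSpec
    spec_b: SnpSpec

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (3, 3, 2):
            raise ValueError("two-locus table must be 3x3x2")
        if (self.counts < 0).any():
            raise ValueError("negative cell count")

    @property
    def cases(self) -> np.ndarray:
        return self.counts[:, :, 0]

    @property
    def controls(self) -> np.ndarray:
        return self.counts[:, :, 1]

    @property
    def n_cases(self) -> int:
        return int(self.cases.sum())

    @property
    def n_controls(self) -> int:
        return int(self.controls.sum())

    def cell(self, ga: int, gb: int) -> tuple[int, int]:
        """(cases, controls) in one joint-dosage cell."""
        return int(self.counts[ga, gb, 0]), int(self.counts[ga, gb, 1])

    def marginal(self, which: str) -> GenotypeCounts:
        """Single-SNP counts on the pairwise-complete subset ('a' or 'b')."""
        if which == "a":
            return GenotypeCounts(self.spec_a.name, self.cases.sum(axis=1), self.controls.sum(axis=1))
        if which == "b":
            return GenotypeCounts(self.spec_b.name, self.cases.sum(axis=0), self.controls.sum(axis=0))
        raise ValueError("which must be 'a' or 'b'")

    def transposed(self) -> "TwoLocusTable":
        """Same data with the roles of SNP A and SNP B swapped."""
        return TwoLocusTable(self.counts.transpose(1, 0, 2).copy(), self.spec_b, self.spec_a)

    def __add__(self, other: "TwoLocusTable") -> "TwoLocusTable":
        if (self.spec_a, self.spec_b) != (other.spec_a, other.spec_b):
            raise ValueError("cannot add tables over different SNP pairs")
        return TwoLocusTable(self.counts + other.counts, self.spec_a, self.spec_b)

    def genotype_label(self, ga: int, gb: int) -> str:
        return self.spec_a.genotype_label(ga) + self.spec_b.genotype_label(gb)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ga, gb in GENOTYPE_ORDER:
            nc, nn = self.cell(ga, gb)
            rows.append(
                {
                    "genotype_a": self.spec_a.genotype_label(ga),
                    "genotype_b": self.spec_b.genotype_label(gb),
                    "n_cases": nc,
                    "n_controls": nn,
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

_ID_ALIASES = ("id", "iid", "sample", "subject", "sample_id")
_SEX_ALIASES = ("sex", "gender")
_AGE_ALIASES = ("age", "age_years")
_STATUS_ALIASES = ("status", "af", "affection", "phenotype", "pheno", "case")


def _parse_code(value, what: str, row: int) -> int | None:
    text = str(value).strip()
    if text == "" or text.lower() in ("na", "nan", "none"):
        return None
    try:
        code = int(float(text))
    except ValueError:
        raise InvalidCodingError(f"row {row}: {what} code {value!r} is not numeric") from None
    if code not in (1, 2):
        raise InvalidCodingError(f"row {row}: {what} code {code} outside {{1, 2}}")
    return code


def _parse_age(value) -> float | None:
    text = str(value).strip()
    if text == "" or text.lower() in ("na", "nan", "none", "."):
        return None
    age = float(text)
    if age < 0:
        raise InvalidCodingError(f"negative age {age}")
    return age


def read_cohort(
    path: str | Path,
    specs: Sequence[SnpSpec],
    dialect: str = "table",
    columns: Mapping[str, str] | None = None,
    label: str = "",
    map_path: str | Path | None = None,
) -> Cohort:
    """Read a subject-level genotype table into a :class:`Cohort`.

    Parameters
    ----------
    path
        Delimited subject table (``dialect="table"``) or PLINK text PED file
        (``dialect="ped"``; the companion ``.map`` is found by suffix swap or
        via *map_path*).
    specs
        SNP specs, in column order for positional/PED binding.
    columns
        Optional mapping of logical names (``id``, ``sex``, ``age``,
        ``status``, or a SNP name) to header names.
    """
    path = Path(path)
    if dialect == "ped":
        return _read_ped(path, specs, label=label, map_path=map_path)
    if dialect != "table":
        raise ValueError(f"unknown dialect {dialect!r}")

    sep = "," if path.suffix.lower() == ".csv" else None
    df = pd.read_csv(path, sep=sep, engine="python", dtype=str, keep_default_na=False)
    if df.empty and df.columns.size == 0:
        return Cohort([], {s.name: s for s in specs}, label=label)

    lower = {c.lower(): c for c in df.columns}
    columns = dict(columns or {})

    def resolve(logical: str, aliases: Iterable[str]) -> str | None:
        if logical in columns:
            return columns[logical]
        for alias in aliases:
            if alias in lower:
                return lower[alias]
        return None

    col_id = resolve("id", _ID_ALIASES)
    col_sex = resolve("sex", _SEX_ALIASES)
    col_age = resolve("age", _AGE_ALIASES)
    col_status = resolve("status", _STATUS_ALIASES)
    snp_cols = {s.name: resolve(s.name, (s.name.lower(),)) for s in specs}

    if col_id is None or col_status is None or any(c is None for c in snp_cols.values()):
        # positional fallback: id, sex, age, status, genotype columns in spec order
        df = pd.read_csv(path, sep=sep, engine="python", dtype=str, header=None,
                         keep_default_na=False)
        needed = 4 + len(specs)
        if df.shape[1] < needed:
            raise InvalidCodingError(
                f"{path}: expected at least {needed} columns (id, sex, age, status, genotypes)"
            )
        first = str(df.iloc[0, 3]).strip() if len(df) else ""
        if first and first not in ("1", "2"):  # stray header row
            df = df.iloc[1:].reset_index(drop=True)
            logger.info("%s: skipped unrecognised header row", path)
        df.columns = [f"c{i}" for i in range(df.shape[1])]
        col_id, col_sex, col_age, col_status = "c0", "c1", "c2", "c3"
        snp_cols = {s.name: f"c{4 + i}" for i, s in enumerate(specs)}

    spec_map = {s.name: s for s in specs}
    subjects: list[Subject] = []
    n_missing = 0
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rowd = dict(zip(df.columns, row))
        status = _parse_code(rowd[col_status], "status", i)
        if status is None:
            raise InvalidCodingError(f"row {i}: missing affection status")
        sex = _parse_code(rowd[col_sex], "sex", i) if col_sex else None
        age = _parse_age(rowd[col_age]) if col_age else None
        calls: dict[str, GenotypeCall] = {}
        for name, col in snp_cols.items():
            call = GenotypeCall.parse(str(rowd[col]), spec_map[name])
            if call.is_missing:
                n_missing += 1
            calls[name] = call
        subjects.append(Subject(str(rowd[col_id]).strip(), sex, age, status, calls))
    if n_missing:
        logger.info("%s: %d missing genotype calls", path, n_missing)
    return Cohort(subjects, spec_map, label=label or path.stem)


def _read_ped(
    path: Path,
    specs: Sequence[SnpSpec],
    label: str = "",
    map_path: str | Path | None = None,
) -> Cohort:
    """PLINK text PED: FID IID PAT MAT SEX PHENO + two allele columns per SNP."""
    map_path = Path(map_path) if map_path else path.with_suffix(".map")
    snp_order: list[str] = []
    if map_path.exists():
        for line in map_path.read_text().splitlines():
            parts = line.split()
            if parts:
                snp_order.append(parts[1])
    else:
        snp_order = [s.name for s in specs]
    spec_map = {s.name: s for s in specs}
    missing_specs = [n for n in snp_order if n not in spec_map]
    if missing_specs:
        raise KeyError(f"no SnpSpec for PED SNPs {missing_specs}")

    subjects: list[Subject] = []
    for i, line in enumerate(path.read_text().splitlines(), start=1):
        parts = line.split()
        if not parts:
            continue
        if len(parts) < 6 + 2 * len(snp_order):
            raise InvalidCodingError(f"row {i}: truncated PED line")
        _fid, iid, _pat, _mat, sex_s, pheno_s = parts[:6]
        sex = _parse_code(sex_s, "sex", i) if sex_s != "0" else None
        status = _parse_code(pheno_s, "status", i)
        if status is None:
            raise InvalidCodingError(f"row {i}: missing phenotype")
        calls = {}
        for k, name in enumerate(snp_order):
            a1, a2 = parts[6 + 2 * k], parts[7 + 2 * k]
            calls[name] = GenotypeCall.parse(a1 + a2, spec_map[name])
        subjects.append(Subject(iid, sex, None, status, calls))
    return Cohort(subjects, spec_map, label=label or path.stem)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort in the subject-table layout (round-trips with read_cohort)."""
    path = Path(path)
    names = list(cohort.specs)
    with path.open("w") as fh:
        fh.write("\t".join(["id", "sex", "age", "status", *names]) + "\n")
        for s in cohort.subjects:
            age = "" if s.age is None else (f"{s.age:g}")
            sex = "" if s.sex is None else str(s.sex)
            calls = [str(s.calls.get(n, GenotypeCall.missing())) for n in names]
            fh.write("\t".join([s.id, sex, age, str(s.status), *calls]) + "\n")


def read_counts(path: str | Path, spec_a: SnpSpec, spec_b: SnpSpec) -> TwoLocusTable:
    """Read a pre-aggregated nine-row two-locus count table.

    Columns: genotype_a, genotype_b, n_cases, n_controls (header optional).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    cols = [c.lower() for c in df.columns]
    if "n_cases" not in cols:  # headerless
        df = pd.read_csv(path, sep=None, engine="python", dtype=str, header=None,
                         keep_default_na=False)
        df.columns = ["genotype_a", "genotype_b", "n_cases", "n_controls"][: df.shape[1]]
    else:
        df.columns = cols
    counts = np.zeros((3, 3, 2), dtype=int)
    for _, row in df.iterrows():
        ga = dosage(GenotypeCall.parse(row["genotype_a"], spec_a), spec_a)
        gb = dosage(GenotypeCall.parse(row["genotype_b"], spec_b), spec_b)
        if ga is None or gb is None:
            raise InvalidAlleleError(f"unparseable genotype row {row.tolist()}")
        counts[ga, gb, 0] += int(row["n_cases"])
        counts[ga, gb, 1] += int(row["n_controls"])
    return TwoLocusTable(counts, spec_a, spec_b)


def crosstab_single(cohort: Cohort, snp: str) -> GenotypeCounts:
    """Complete-case genotype counts by dosage and status for one SNP."""
    spec = cohort.specs[snp]
    cases = np.zeros(3, dtype=int)
    controls = np.zeros(3, dtype=int)
    for s in cohort.subjects:
        d = dosage(s.calls.get(snp, GenotypeCall.missing()), spec)
        if d is None:
            continue
        (cases if s.is_case else controls)[d] += 1
    return GenotypeCounts(snp, cases, controls)


def crosstab_pair(cohort: Cohort, snp_a: str, snp_b: str) -> TwoLocusTable:
    """3x3x2 counts over subjects with both calls present."""
    spec_a, spec_b = cohort.specs[snp_a], cohort.specs[snp_b]
    counts = np.zeros((3, 3, 2), dtype=int)
    for s in cohort.subjects:
        da = dosage(s.calls.get(snp_a, GenotypeCall.missing()), spec_a)
        db = dosage(s.calls.get(snp_b, GenotypeCall.missing()), spec_b)
        if da is None or db is None:
            continue
        counts[da, db, 0 if s.is_case else 1] += 1
    return TwoLocusTable(counts, spec_a, spec_b)


# ---------------------------------------------------------------------------
# result formatting
# ---------------------------------------------------------------------------

def format_or(or_value: float, ci_low: float, ci_high: float) -> str:
    """`4.85 (3.60-6.53)` style odds-ratio formatting (2 decimals)."""
    return f"{or_value:.2f} ({ci_low:.2f}-{ci_high:.2f})"


def format_percent(count: int, total: int) -> str:
    """Column percentage to 1 decimal, e.g. 148/2020 -> ``7.3%``."""
    if total == 0:
        return "0.0%"
    return f"{100.0 * count / total:.1f}%"


def write_results(
    tables: Mapping[str, pd.DataFrame],
    outdir: str | Path,
    fmt: str = "tsv",
    summary: Mapping | None = None,
) -> list[Path]:
    """Write result tables as delimited text plus one JSON summary.

    Empty tables produce header-only files.  Returns the written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sep = "," if fmt == "csv" else "\t"
    ext = "csv" if fmt == "csv" else "tsv"
    written: list[Path] = []
    for name, df in tables.items():
        p = outdir / f"{name}.{ext}"
        df.to_csv(p, sep=sep, index=False, float_format="%.6g")
        written.append(p)
    summary_path = outdir / "summary.json"
    payload = {"tables": sorted(tables)}
    if summary:
        payload.update(summary)
    summary_path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
    written.append(summary_path)
    return written
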
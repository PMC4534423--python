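"""Bundled example count tables.

Aggregated nine-cell two-locus genotype counts for three atrial-fibrillation
GWAS loci replicated in Chinese Han case-control cohorts: rs2106261 (ZFHX3,
risk allele A), rs2200733 (PITX2c locus, risk allele T) and rs3807989
(CAV1, risk allele G).  The rs2106261 x rs2200733 pair is available per
population (discovery, two replications) and combined (2,020 cases /
5,315 controls); the CAV1 pairs cover the 1,578 / 2,389 subset with all
three SNPs typed.
"""

from __future__ import annotations

from importlib import resources

from ..io import SnpSpec, TwoLocusTable, read_counts

RS2106261 = SnpSpec("rs2106261", "G", "A")
RS2200733 = SnpSpec("rs2200733", "C", "T")
RS3807989 = SnpSpec("rs3807989", "A", "G")

SPECS = {s.name: s for s in (RS2106261, RS2200733, RS3807989)}

_TABLES: dict[str, tuple[SnpSpec, SnpSpec]] = {
    "rs2106261_rs2200733_discovery": (RS2106261, RS2200733),
    "rs2106261_rs2200733_replication1": (RS2106261, RS2200733),
    "rs2106261_rs2200733_replication2": (RS2106261, RS2200733),
    "rs2106261_rs2200733_combined": (RS2106261, RS2200733),
    "rs2106261_rs3807989": (RS2106261, RS3807989),
    "rs2200733_rs3807989": (RS2200733, RS3807989),
}


def available() -> list[str]:
    """Names accepted by :func:`load_counts`."""
    return sorted(_TABLES)


def load_counts(name: str) -> TwoLocusTable:
    """Load one bundled two-locus count table by name."""
    if name not in _TABLES:
        raise KeyError(f"unknown table {name!r}; available: {available()}")
    spec_a, spec_b = _TABLES[name]
    with resources.as_file(resources.files(__package__) / f"{name}.tsv") as path:
        return read_counts(path, spec_a, spec_b)
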
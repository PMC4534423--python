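"""Exception hierarchy shared by all analysis stages."""


class EpisnpError(Exception):
    """Base class for all package errors."""


class InvalidCodingError(EpisnpError):
    """A sex or affection-status code outside the 1/2 convention."""


class InvalidAlleleError(EpisnpError):
    """A genotype character not among the SNP's two declared alleles."""


class DuplicateSubjectError(EpisnpError):
    """The same subject id appears more than once in a cohort."""


class DegenerateTableError(EpisnpError):
    """A contingency table with an empty row, column, or stratum."""


class ReferenceDegenerateError(DegenerateTableError):
    """The chosen reference genotype cell is empty in cases or controls."""


class SeparationError(EpisnpError):
    """Complete or quasi-complete separation in a logistic fit."""


class RankError(EpisnpError):
    """Singular information matrix (collinear or constant predictors)."""


class MissingCovariateError(EpisnpError):
    """Covariate adjustment requested on data without subject-level covariates."""


class ParameterError(EpisnpError):
    """Simulation or configuration parameters outside their valid domain."""
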
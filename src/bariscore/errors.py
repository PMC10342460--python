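"""Exception hierarchy shared across the pipeline."""


class BariscoreError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(BariscoreError, ValueError):
    """An argument violates a documented precondition."""


class UnknownSNPError(BariscoreError, KeyError):
    """An rsid was requested that the manifest/matrix does not contain."""


class AlleleMismatchError(BariscoreError, ValueError):
    """A genotype call uses an allele letter outside the manifest's ref/alt pair."""

    def __init__(self, message: str, records: list | None = None):
        super().__init__(message)
        self.records = records or []


class InsufficientDataError(BariscoreError):
    """Too few complete-case observations to fit the requested model."""


class DegenerateDesignError(BariscoreError):
    """The design matrix is rank deficient or a genetic column is constant."""


class AllModelsSkippedError(BariscoreError):
    """Every inheritance model was non-estimable for a SNP."""


class EmptyRiskScoreError(BariscoreError):
    """No significant QC-passing SNPs were available to build a risk score."""


class EmptyCategoryError(BariscoreError):
    """A score category is empty, so a two-group comparison is impossible."""
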
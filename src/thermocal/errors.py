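"""Exception hierarchy for thermocal."""


class ThermocalError(Exception):
    """Base class for all thermocal-specific errors."""


class FormatError(ThermocalError):
    """A file does not conform to the expected schema or encoding."""


class MetadataError(FormatError):
    """Required metadata (e.g. a sidecar key) is missing or invalid."""


class SingularFitError(ThermocalError):
    """The regression design matrix is rank deficient.

    Carries the names of the terms involved in the collinearity when they
    can be identified.
    """

    def __init__(self, message: str, collinear_terms: tuple[str, ...] = ()):
        super().__init__(message)
        self.collinear_terms = collinear_terms


class TrainingDivergenceError(ThermocalError):
    """Network training produced a non-finite loss."""


class UndefinedStatisticError(ThermocalError):
    """A statistic is undefined for the given input (e.g. zero variance)."""
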
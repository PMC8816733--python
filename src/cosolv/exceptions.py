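"""Exception and warning hierarchy for :mod:`cosolv`."""


class CosolvError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(CosolvError):
    """An input table is missing required columns."""


class ParseError(CosolvError):
    """An input file could not be parsed (empty file, non-numeric cell, ...)."""


class ValidationError(CosolvError):
    """A record or dataset violates a domain invariant."""


class DomainError(CosolvError, ValueError):
    """A numeric argument lies outside the physically meaningful domain."""


class FitError(CosolvError):
    """A model fit failed."""


class DegenerateDesignError(FitError):
    """The regression design is degenerate (e.g. all x-values identical)."""


class AnchorMissingError(FitError):
    """A required neat-solvent anchor record is absent from the dataset."""


class RankDeficiencyError(FitError):
    """The regression design matrix is rank deficient."""


class ConvergenceError(CosolvError):
    """An iterative solver failed to converge."""


class QuantitationError(CosolvError):
    """Inverse prediction from a calibration curve produced an invalid result."""


class ConfigurationError(CosolvError):
    """A model was invoked with an incomplete or inconsistent configuration."""


class AlignmentError(CosolvError):
    """Two series that must share an index (f1 grid, temperatures) do not."""


class StateError(CosolvError):
    """An operation was called before its prerequisites (e.g. an unfitted model)."""


class ExtrapolationWarning(UserWarning):
    """A prediction was requested outside the calibrated/valid range."""
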
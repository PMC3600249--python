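"""Exception hierarchy for cbcscore.

All package-specific failures derive from :class:`CbcScoreError` so callers
can catch one type at pipeline level while tests assert on the specific
subclass.
"""


class CbcScoreError(Exception):
    """Base class for all cbcscore errors."""


class ParameterMismatchError(CbcScoreError):
    """A measurement was standardized against a reference range for a
    different CBC parameter."""


class MissingValueError(CbcScoreError):
    """A Z-value was requested for a measurement whose value is absent.

    Callers are expected to filter missing measurements before
    standardization; this error is a contract violation, not a data state.
    """


class UnscorableRecordError(CbcScoreError):
    """No selected parameter has a present value, so no score exists.

    Raised rather than returning a silent zero: a zero score is a
    meaningful clinical statement (all parameters at reference mean), not a
    missing-data sentinel.
    """


class UndefinedCorrelationError(CbcScoreError):
    """Rank correlation is undefined because one vector has zero rank
    variance (all values tied)."""


class InsufficientSampleError(CbcScoreError):
    """Too few complete observation pairs for the requested test."""


class OutOfStudyRangeError(CbcScoreError):
    """Survival time falls outside the study's [1, 365]-day window."""


class ValidationError(CbcScoreError):
    """A configuration object or input table failed validation."""
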
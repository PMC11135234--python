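"""Exception hierarchy for uiknmf.

All package errors derive from :class:`UikNmfError` so callers can catch one
base class; subclasses distinguish the failure mode (bad matrix, bad rank,
degenerate curve, ...).
"""


class UikNmfError(Exception):
    """Base class for all uiknmf errors."""


class ValidationError(UikNmfError):
    """Input matrix violates a contract (negative/NaN entries, zero rows, duplicate labels)."""


class DimensionError(UikNmfError):
    """Matrix shapes do not conform."""


class RankError(UikNmfError):
    """Requested factorization rank is invalid for the input shape."""


class ArgumentError(UikNmfError):
    """A scalar argument is outside its admissible range."""


class DegenerateCurveError(UikNmfError):
    """Curve is constant: neither trend nor convexity is defined."""


class NoKneeError(UikNmfError):
    """Curve has no knee (e.g. all points collinear)."""


class SchemeError(UikNmfError):
    """A holdout scheme leaves a row or column with too few observed entries."""


class GenerationError(UikNmfError):
    """Synthetic-data generation could not satisfy its constraints."""


class EmptyResultError(UikNmfError):
    """Preprocessing removed every feature."""


class ConfigError(UikNmfError):
    """Pipeline configuration is invalid."""
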
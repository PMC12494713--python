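"""Exception taxonomy for the drift-connectivity pipeline.

All package errors derive from :class:`DriftConnError` so callers can catch
one base class; subclasses distinguish bad configuration, malformed input
files, numerically degenerate designs, and analysis preconditions.
"""


class DriftConnError(Exception):
    """Base class for all errors raised by driftconn."""


class ConfigurationError(DriftConnError):
    """A parameter, label, or design specification is invalid."""


class FormatError(DriftConnError):
    """An input file is malformed or inconsistent (shape, affine, NaNs)."""


class NumericalError(DriftConnError):
    """A numerically degenerate problem (e.g. rank-deficient design)."""


class AnalysisError(DriftConnError):
    """A statistical precondition is violated (e.g. zero-variance seed)."""


class DomainError(DriftConnError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""
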
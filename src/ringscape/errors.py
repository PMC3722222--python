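"""Exception taxonomy shared across the pipeline stages."""


class RingscapeError(Exception):
    """Base class for all package errors."""


class FormatError(RingscapeError):
    """An on-disk representation could not be parsed."""


class ValidationError(RingscapeError):
    """In-memory data violates a documented invariant."""


class ConfigurationError(RingscapeError):
    """Requested parameters are infeasible or inconsistent."""


class DecompositionError(RingscapeError):
    """A matrix factorization could not be computed (e.g. degenerate series)."""


class StatisticsError(RingscapeError):
    """A statistical operation has too little data to be defined."""
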
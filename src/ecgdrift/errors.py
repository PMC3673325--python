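"""Exception hierarchy for the toolkit.

All library errors derive from :class:`EcgDriftError` so callers (and the CLI)
can catch one base class; specific subclasses encode the failure mode.
"""


class EcgDriftError(Exception):
    """Base class for all errors raised by ecgdrift."""


class InputError(EcgDriftError):
    """Invalid argument shapes, lengths, or ranges."""


class DataError(EcgDriftError):
    """Non-finite or otherwise unusable sample data."""


class ConfigError(EcgDriftError):
    """Invalid configuration value or unknown option."""


class FormatError(EcgDriftError):
    """Malformed input file (wrong columns, non-uniform sampling, ...)."""


class RankError(EcgDriftError):
    """Degenerate covariance: whitening is impossible."""


class PoleError(EcgDriftError):
    """Transfer-function denominator evaluates to (numerically) zero."""


class DivergenceError(EcgDriftError):
    """Adaptive filter weights blew past the divergence guard."""

    def __init__(self, message: str, index: int):
        super().__init__(message)
        self.index = index


class StageError(EcgDriftError):
    """Failure inside a named pipeline stage; wraps the underlying error."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


class RankDeficiencyWarning(UserWarning):
    """Eigenvalues below the variance floor were dropped during whitening."""
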
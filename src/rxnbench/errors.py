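"""Exception types shared across the pipeline."""


class RxnBenchError(Exception):
    """Base class for all package errors."""


class InvalidMoleculeError(RxnBenchError):
    """A string could not be parsed as a molecule."""


class NotDecodableError(RxnBenchError):
    """A SELFIES string (e.g. the '?' fallback) cannot be decoded."""


class TokenizationError(RxnBenchError):
    """A string violates the token grammar (e.g. a dangling '[')."""


class ConfigurationError(RxnBenchError):
    """Invalid or inconsistent configuration values."""


class CoverageError(RxnBenchError):
    """An embedding table does not cover the model vocabulary."""


class UndefinedMetricError(RxnBenchError):
    """A metric was requested on an empty or degenerate input."""
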
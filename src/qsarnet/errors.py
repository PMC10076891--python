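"""Exception hierarchy.

The CLI maps these onto exit codes: configuration problems exit 2, data
problems (parsing, validation) exit 3, training divergence exits 4.
"""


class QsarNetError(Exception):
    """Base class for all package errors."""


class ConfigError(QsarNetError):
    """Invalid or malformed run configuration."""


class DataError(QsarNetError):
    """Problem with input data (missing files, bad shapes, ...)."""


class ParseError(DataError):
    """A file could not be parsed; the message names the offending cell."""


class ValidationError(DataError):
    """Input violates a documented precondition or invariant."""


class TrainingError(QsarNetError):
    """Optimization diverged (NaN/Inf cost) or otherwise failed."""
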
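"""Exception types raised across the package."""


class SimnmfError(Exception):
    """Base class for all package-specific errors."""


class DimensionError(SimnmfError):
    """Operand shapes do not conform; the message names the offending operand."""


class DomainError(SimnmfError):
    """A matrix entry lies outside its permitted domain (e.g. non-binary association)."""


class NumericError(SimnmfError):
    """Non-finite values encountered where finite arithmetic is required."""


class ConfigurationError(SimnmfError):
    """Hyperparameters or run configuration are invalid for the given data."""


class AlignmentError(SimnmfError):
    """Identifier sets of the input matrices cannot be reconciled."""


class ParseError(SimnmfError):
    """A delimited-text matrix could not be parsed; the message carries cell coordinates."""


class UndefinedMetricError(SimnmfError):
    """A ranking metric is undefined for the given labels (e.g. single-class AUC)."""
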
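"""Exception types shared across the package."""

import numpy as np


class MBLDAError(Exception):
    """Base class for package errors."""


class ConfigError(MBLDAError, ValueError):
    """Invalid configuration or invalid inputs to an operation."""


class DimensionError(ConfigError):
    """Feature-vector dimension does not match the model state."""


class StreamFormatError(MBLDAError, ValueError):
    """A stream file could not be parsed; the message names the line."""

    def __init__(self, message, line=None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class IllConditionedError(MBLDAError, np.linalg.LinAlgError):
    """A covariance matrix is singular or numerically ill-conditioned."""
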
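"""Exception hierarchy shared across the toolkit.

Exit-code mapping for the CLI: ConfigError -> 2, DataError (and subclasses)
-> 3, ConvergenceError -> 4.
"""


class CarodopError(Exception):
    """Base class for all package errors."""


class ConfigError(CarodopError):
    """Invalid configuration or precondition violation."""


class GeometryError(ConfigError):
    """Probe/vessel geometry outside the valid operating range."""


class DataError(CarodopError):
    """Malformed, inconsistent, or unusable input data."""


class FormatError(DataError):
    """File does not match the expected on-disk schema."""


class AliasingError(DataError):
    """A velocity exceeds the Nyquist limit for the configured PRF."""


class AlignmentError(DataError):
    """Clock synchronization could not be established."""


class ConvergenceError(CarodopError):
    """Iterative model fit failed to converge."""
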
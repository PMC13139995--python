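"""Exception hierarchy.

``ConfigError`` covers bad parameters and malformed run configuration
(CLI exit code 2); ``DataError`` covers malformed or inconsistent input
data (CLI exit code 3).
"""


class MethylantError(Exception):
    """Base class for all package errors."""


class ConfigError(MethylantError):
    """Invalid configuration or parameter value."""


class DataError(MethylantError):
    """Malformed, inconsistent, or infeasible input data."""


class PackingError(ConfigError):
    """Requested simulated features do not fit in the genome."""
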
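"""Exception hierarchy.

Exit-code mapping used by the CLI: ParameterError/ConfigError -> 2,
DataError/FormatError -> 3, FitError/PowerRunError -> 4.
"""


class FolliclePowerError(Exception):
    """Base class for all package errors."""


class ParameterError(FolliclePowerError, ValueError):
    """Invalid parameter value (negative intensity, bad mixture weights, ...)."""


class ConfigError(FolliclePowerError, ValueError):
    """Malformed or incomplete pipeline configuration."""


class DataError(FolliclePowerError, ValueError):
    """Structurally invalid observation data (duplicates, non-nested labels, ...)."""


class FormatError(FolliclePowerError, ValueError):
    """Malformed on-disk table (missing column, unparseable value)."""


class FitError(FolliclePowerError, RuntimeError):
    """Model fit failed (singular design, non-convergence)."""


class PowerRunError(FolliclePowerError, RuntimeError):
    """Monte-Carlo power run deemed unreliable (too many fit failures)."""
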
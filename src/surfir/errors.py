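"""Exception hierarchy.

``ConfigError`` maps to CLI exit code 2, ``DataError`` to exit code 3.
"""


class SurfirError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(SurfirError):
    """Invalid parameter, configuration value or file."""


class DataError(SurfirError):
    """Input data violates a contract (unbalanced design, empty selection, ...)."""


class DegenerateDataError(DataError):
    """Data carries no usable variation (all-equal responses, constant matrix)."""


class UndefinedMetricError(DataError):
    """A metric's defining ratio has a zero denominator (zero noise, zero mean, ...)."""


class RankDeficiencyError(DataError):
    """Requested latent variables exceed what the data can support."""

    def __init__(self, requested: int, max_usable: int):
        self.requested = requested
        self.max_usable = max_usable
        super().__init__(
            f"requested {requested} latent variables but the data supports "
            f"at most {max_usable}"
        )
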
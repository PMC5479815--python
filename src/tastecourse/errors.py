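"""Exception types shared across the package."""


class TastecourseError(ValueError):
    """Base class for all package-specific errors."""


class InputError(TastecourseError):
    """Raised when an input matrix, gene set, or design is malformed."""


class ConfigError(TastecourseError):
    """Raised when a simulation or run configuration is invalid."""
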
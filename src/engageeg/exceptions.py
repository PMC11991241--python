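"""Exception hierarchy shared across the pipeline stages."""


class EngagEEGError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EngagEEGError, ValueError):
    """A parameter or configuration value is invalid."""


class ValidationError(EngagEEGError, ValueError):
    """An input record violates its contract (shape, range, keys)."""


class DegenerateInputError(EngagEEGError, ValueError):
    """Input is structurally valid but carries no usable information
    (e.g. all in-game metrics constant across levels)."""


class DecompositionError(EngagEEGError, RuntimeError):
    """A matrix decomposition (ICA) failed, e.g. on rank-deficient data."""
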
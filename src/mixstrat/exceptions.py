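"""Exception types shared across the package."""


class MixstratError(Exception):
    """Base class for all package-specific errors."""


class MissingDataError(MixstratError, ValueError):
    """A required measurement or field is absent (NaN/None)."""


class ConfigError(MixstratError, ValueError):
    """Invalid generator, threshold, or pipeline configuration."""


class DegenerateReferenceError(MixstratError, ValueError):
    """Control reference cannot be fit (fewer than two values, or zero spread)."""


class InputError(MixstratError, ValueError):
    """Malformed input values (non-finite measurements, unknown labels, ...)."""
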
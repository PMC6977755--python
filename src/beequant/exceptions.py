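"""Exception types raised across the package."""


class BeequantError(ValueError):
    """Base class for domain errors."""


class InfeasibleConfigurationError(BeequantError):
    """Rejection sampling could not satisfy the requested constraints."""


class FormatError(BeequantError):
    """Malformed input record (e.g. an invalid quality character)."""


class DegenerateSampleError(BeequantError):
    """A sample carries no usable signal (all-zero counts or mass)."""


class CalibrationInputError(BeequantError):
    """Specimen and read tables disagree in a way that prevents calibration."""


class UndefinedStatisticError(BeequantError):
    """A statistic is undefined for the given input (e.g. constant vectors)."""
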
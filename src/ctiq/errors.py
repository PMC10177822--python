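"""Exception hierarchy.

All package errors derive from :class:`CTIQError` so callers (and the CLI)
can distinguish data problems (exit code 1) from configuration problems
(exit code 2).
"""


class CTIQError(Exception):
    """Base class for all errors raised by ctiq."""


class ConfigError(CTIQError):
    """A parameter violates an operation's precondition."""


class SizingError(CTIQError):
    """A geometric request does not fit inside the raster."""


class SamplingError(CTIQError):
    """A profile sample point falls outside the image raster."""


class DegenerateInputError(CTIQError):
    """Input is valid but the requested quantity is undefined on it
    (e.g. SNR on a noise-free image)."""


class DegenerateProfileError(DegenerateInputError):
    """A profile is flat or inverted: baselines cannot be assigned."""


class UndefinedStatisticError(DegenerateInputError):
    """A statistic is undefined on this table (zero between-item variance,
    chance agreement probability of one, ...)."""


class DataFormatError(CTIQError):
    """A file does not match the expected schema."""
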
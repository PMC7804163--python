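"""Exception hierarchy shared across the pipeline.

The CLI maps these onto process exit codes: configuration problems -> 2,
data-format problems -> 3, numerical failures -> 4.
"""


class DrsError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(DrsError):
    """Invalid configuration or invalid parameter values."""


class DataFormatError(DrsError):
    """Malformed input files or inconsistent array layouts."""


class MergeError(DataFormatError):
    """VIS/NIR channels cannot be merged (missing overlap coverage)."""


class NumericalError(DrsError):
    """A numerical stage failed (degenerate input, empty selection, ...)."""


class CalibrationError(NumericalError):
    """Raw-spectrum calibration failed (non-positive denominator)."""
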
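"""Exception hierarchy for the PAWS pipeline.

Trial-level analysis failures (no movement, no qualifying peak) are
recoverable: batch drivers catch :class:`TrialError` subclasses and record
the trial as rejected rather than aborting the run.
"""


class PawsError(Exception):
    """Base class for all package errors."""


class ConfigError(PawsError):
    """Invalid configuration value or combination."""


class FormatError(PawsError):
    """Input file does not match the expected format (e.g. missing column)."""


class ParseError(PawsError):
    """A cell could not be parsed; message carries the offending row."""


class TrialError(PawsError):
    """A single trial failed analysis; batch processing may continue."""


class TooShortError(TrialError):
    """Trajectory shorter than the smoothing window."""


class NoMovementError(TrialError):
    """No sustained supra-threshold movement found in the trajectory."""


class NoPeakError(TrialError):
    """No qualifying paw-height peak found inside the movement window."""


class ZeroVarianceError(PawsError):
    """A feature column has zero variance and cannot be standardized."""


class ModelError(PawsError):
    """Model fitting or (de)serialization failure."""
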
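"""Exception hierarchy for piezosleep.

All package-specific failures derive from :class:`PiezoSleepError` so callers
can catch one base class; the leaf classes distinguish bad parameters from
malformed data from numerically degenerate inputs.
"""


class PiezoSleepError(Exception):
    """Base class for all piezosleep errors."""


class FormatError(PiezoSleepError, ValueError):
    """A recording file or config could not be parsed."""


class LayoutError(PiezoSleepError, ValueError):
    """Sensor layout / channel-count contract violated."""


class ParameterError(PiezoSleepError, ValueError):
    """An argument is outside its documented domain."""


class WindowError(PiezoSleepError, ValueError):
    """A smoothing window does not fit the data series (N < 2W+1)."""


class CalibrationError(PiezoSleepError, ValueError):
    """Not enough empty-bed data to calibrate the presence threshold."""


class DegenerateSignalError(PiezoSleepError, ArithmeticError):
    """A centered or flat series made an amplitude-ratio denominator vanish."""


class AlignmentError(PiezoSleepError, ValueError):
    """Detector report and ground truth are on different period grids."""


class ConfigError(PiezoSleepError, ValueError):
    """A simulation configuration violates its invariants."""
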
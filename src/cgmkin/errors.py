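"""Exception hierarchy for cgmkin.

Every error raised on a user-facing path derives from CgmError so callers
(and the CLI) can distinguish model/data problems from programming bugs.
"""


class CgmError(Exception):
    """Base class for all cgmkin errors."""


class FormatError(CgmError):
    """A file could not be parsed; the message names the offending section."""


class ValidationError(CgmError):
    """Input values violate a documented precondition."""


class GeometryError(CgmError):
    """A geometric construction is degenerate (collinear markers, chord
    offset exceeding the segment length, coincident markers)."""


class CalibrationError(CgmError):
    """The static trial cannot produce a calibration."""


class ConfigurationError(CgmError):
    """A selectable method is missing its required configuration."""


class GenerationError(CgmError):
    """The synthetic generator was driven into an inconsistent state."""


class ParallelExecutionError(CgmError):
    """A worker failed; the message carries the item range context."""
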
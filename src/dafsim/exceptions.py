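"""Exception hierarchy for dafsim.

All package errors derive from :class:`DafsimError` so callers can catch
everything with one clause; the subclasses mirror the distinct failure
modes of the signal chain (shape problems, out-of-range requests,
degenerate signals, bad configuration, malformed files).
"""


class DafsimError(Exception):
    """Base class for all dafsim errors."""


class DimensionError(DafsimError, ValueError):
    """Array shape or bin count does not match what the operation requires."""


class RangeError(DafsimError, ValueError):
    """A requested index, window, or interval lies outside the available data."""


class DegenerateInputError(DafsimError, ValueError):
    """Input is formally valid but carries no usable signal (e.g. zero variance)."""


class ConfigurationError(DafsimError, ValueError):
    """Missing or inconsistent configuration."""


class EstimationError(DafsimError, ValueError):
    """An estimator has no defined value on the given input."""


class InputError(DafsimError, ValueError):
    """Malformed analysis input (unsorted times, non-positive intervals, ...)."""


class FormatError(DafsimError, ValueError):
    """Unsupported or malformed file format."""


class ChannelError(FormatError):
    """Audio has the wrong channel count (mono required)."""


class ValidationError(DafsimError, ValueError):
    """A structured file failed validation; the message names the offending line."""
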
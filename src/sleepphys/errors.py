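"""Exception hierarchy.

Configuration problems (bad parameters, malformed config documents) raise
:class:`ConfigError`; problems with data content (misaligned inputs, files
that do not parse, degenerate signals) raise :class:`DataError` subclasses.
The CLI maps these onto exit codes 2 and 3 respectively.
"""


class SleepPhysError(Exception):
    """Base class for all package errors."""


class ConfigError(SleepPhysError):
    """Invalid parameter value or malformed configuration document."""


class ScheduleError(ConfigError):
    """Inconsistent stimulation/perturbation schedule (offset <= onset etc.)."""


class DataError(SleepPhysError):
    """Problem with the content of the data itself."""


class InsufficientDataError(DataError):
    """Not enough data to compute the requested quantity."""


class AlignmentError(DataError):
    """Inputs that must share a time base or length do not."""


class DegenerateDataError(DataError):
    """Signal is degenerate for the requested operation (zero mean/SD/power)."""


class ThresholdEstimationError(DegenerateDataError):
    """Automatic threshold estimation failed on degenerate features."""
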
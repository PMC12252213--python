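"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError (and
subclasses) -> 3, ConvergenceError -> 4.
"""


class MaxhabError(Exception):
    """Base class for all package errors."""


class ConfigError(MaxhabError):
    """Invalid configuration: unknown option, missing entry, bad value."""


class DataError(MaxhabError):
    """Invalid or inconsistent input data."""


class FormatError(DataError):
    """Malformed file content (e.g. a broken ASCII-grid header)."""


class AlignmentError(DataError):
    """Two rasters do not share the same grid geometry."""


class OutOfBoundsError(DataError):
    """A coordinate falls outside the grid bounding box."""

    def __init__(self, message, points=None):
        super().__init__(message)
        self.points = points


class ValidationError(DataError):
    """A domain invariant is violated (e.g. suitability outside [0, 1])."""


class InsufficientDataError(DataError):
    """Too few observations for the requested statistic."""


class ConvergenceError(MaxhabError):
    """Optimizer failed to reach tolerance within the iteration budget."""

    def __init__(self, message, final_delta=None):
        super().__init__(message)
        self.final_delta = final_delta
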
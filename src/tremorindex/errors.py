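"""Exception hierarchy for tremorindex.

All package-specific failures derive from :class:`TremorIndexError` so callers
can catch one base class at pipeline boundaries.
"""


class TremorIndexError(Exception):
    """Base class for all tremorindex errors."""


class FormatError(TremorIndexError):
    """A device CSV file does not conform to the expected dialect."""


class EmptyRecordingError(TremorIndexError):
    """A file or recording contains no samples."""


class OverlapError(TremorIndexError):
    """Two recordings to be stitched cover overlapping time ranges."""


class IncompatibilityError(TremorIndexError):
    """Recordings to be stitched disagree on sampling rate or hand label."""


class DomainError(TremorIndexError):
    """A parameter is outside its valid domain (e.g. frequency not in 3-12 Hz)."""


class LengthError(TremorIndexError):
    """A signal is too short for the requested wavelet decomposition depth."""

    def __init__(self, message: str, min_length: int | None = None):
        super().__init__(message)
        self.min_length = min_length


class EmptyDataError(TremorIndexError):
    """A statistic was requested on an empty collection of values."""


class DegenerateFitError(TremorIndexError):
    """Too few usable histogram bins to fit a log-log regression line."""


class DegenerateDistributionError(TremorIndexError):
    """A binned PDF has fewer than two occupied bins."""


class UndefinedMomentsError(TremorIndexError):
    """Moments requested on a zero-variance or too-small sample."""


class ValidationError(TremorIndexError):
    """Clinical scores outside the 0-4 item range, or similar bad input."""


class LogDomainError(TremorIndexError):
    """A logarithm of a non-positive quantity was requested."""
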
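"""Exception hierarchy for the pipeline.

Format errors are about file structure (missing columns, unknown labels);
data errors are about the content of a structurally valid file.
"""


class PupilloadError(Exception):
    """Base class for all package errors."""


class FormatError(PupilloadError):
    """A file does not match the expected delimited-text schema."""


class DataError(PupilloadError):
    """Structurally valid input carries inconsistent content."""


class SeriesTooShortError(DataError):
    """A pupil series is shorter than the wavelet decomposition requires."""

    def __init__(self, message: str, required: int | None = None,
                 segment_id: str | None = None):
        super().__init__(message)
        self.required = required
        self.segment_id = segment_id


class SegmentRejectedError(DataError):
    """A segment was rejected during preparation (e.g. too many invalid samples)."""

    def __init__(self, message: str, segment_id: str | None = None,
                 reason: str | None = None):
        super().__init__(message)
        self.segment_id = segment_id
        self.reason = reason


class DegenerateDataError(DataError):
    """A statistic is undefined on the given data (e.g. zero-variance t-test)."""
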
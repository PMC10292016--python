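"""Exception hierarchy shared across the package.

Every error raised on a per-record basis carries enough context (subject id,
point name, row/column) for a batch driver to log it and continue.
"""


class PPGError(Exception):
    """Base class for all domain errors."""


class FormatError(PPGError):
    """Structurally malformed input (ragged rows, wrong column count)."""


class ParseError(PPGError):
    """Non-numeric or otherwise unparseable cell content."""


class ParameterError(PPGError, ValueError):
    """Invalid user-supplied parameter (cutoffs, windows, fractions...)."""


class ConsistencyError(PPGError):
    """Mutually inconsistent components (row-count mismatch, duplicate ids)."""


class LengthError(PPGError):
    """Input vector too short for the requested operation."""


class NoBeatError(PPGError):
    """Fewer than two pulse onsets found in a record."""


class DegenerateBeatError(PPGError):
    """A flat or otherwise degenerate beat segment."""


class DetectionError(PPGError):
    """A required fiducial point could not be located.

    ``point`` names the missing landmark (e.g. ``"w"``, ``"e"``).
    """

    def __init__(self, point: str, message: str | None = None):
        self.point = point
        super().__init__(message or f"could not locate fiducial point {point!r}")


class UndefinedMetricError(PPGError):
    """A performance metric with a zero denominator."""
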
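"""Exception hierarchy.

Configuration problems (bad weights, malformed grade sets, broken file
references) and data problems (missing cells, out-of-range values) are kept
distinct so callers — in particular the CLI — can map them to different
exit codes.
"""


class FamrankError(Exception):
    """Base class for all famrank errors."""


class ConfigError(FamrankError):
    """Invalid configuration: criteria, grade set, effect model or run config."""


class DataError(FamrankError):
    """Invalid or incomplete measurement data."""


class MissingDataError(DataError):
    """A required (condition, criterion) cell has no measurements."""


class OutOfBoundsError(DataError):
    """A value falls outside the scale bounds it is being scored against."""


class ValidationError(DataError):
    """Raised when validation finds fatal issues; carries the issue list."""

    def __init__(self, message: str, issues=None):
        super().__init__(message)
        self.issues = list(issues) if issues is not None else []
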
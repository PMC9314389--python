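"""Exception hierarchy for quollscr."""


class QuollScrError(Exception):
    """Base class for all quollscr errors."""


class SchemaError(QuollScrError):
    """An input table is missing a required column or has the wrong layout."""


class RowError(QuollScrError):
    """A specific input row could not be parsed.

    Carries the 1-based line number of the offending row (header = line 1).
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class IdentityConflictError(QuollScrError):
    """Two linked image sequences carry different individual tags."""


class ParameterError(QuollScrError, ValueError):
    """A parameter value is outside its valid range."""


class InsufficientDataError(QuollScrError):
    """Too few individuals or spatial re-detections to fit an SCR model."""


class MaskError(QuollScrError):
    """The habitat mask is empty, too coarse, or inconsistent with detectors."""


class NotComparableError(QuollScrError):
    """Model fits cannot be ranked together (e.g. different data)."""
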
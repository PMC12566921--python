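"""Exception hierarchy for pipeline failures.

Every stage raises a subclass of :class:`ChartlexError` so callers can
distinguish configuration mistakes from data-integrity problems.
"""


class ChartlexError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ChartlexError):
    """A configuration object violates its invariants."""


class InputError(ChartlexError):
    """Malformed or empty input where content is required."""


class IntegrityError(ChartlexError):
    """Cross-references between artifacts do not line up."""


class IncompleteAnnotationError(ChartlexError):
    """An annotation record is missing a reviewer label."""


class TrainingError(ChartlexError):
    """Model training cannot proceed (e.g. single-class labels)."""


class StageError(ChartlexError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage:{stage}] {message}")
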
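"""Exception hierarchy.

Every labelled error raised by the package derives from
:class:`CrowdScreenError`, so callers (and the CLI) can catch one type.
"""


class CrowdScreenError(Exception):
    """Base class for all package errors."""


class UnknownAllergyError(CrowdScreenError):
    """An allergy label is not one of the seven types or OVERALL."""


class MissingQuestionError(CrowdScreenError):
    """A question id appears in no response record."""


class InvalidTableError(CrowdScreenError):
    """A 2x2 table violates its invariants (negative or all-zero counts)."""


class DegenerateTableError(CrowdScreenError):
    """A 2x2 table has an empty margin, so no odds ratio is estimable."""


class MissingScreeningError(CrowdScreenError):
    """An active question has no screening entry when ranking the pool."""


class EmptyResponsesError(CrowdScreenError):
    """A round was run with no participant responses."""


class StudyError(CrowdScreenError):
    """A round-level failure, annotated with the round index."""


class ConfigError(CrowdScreenError):
    """An invalid crowd-model or study configuration value."""


class ResponseFormatError(CrowdScreenError):
    """Malformed response file; the message lists offending line numbers."""


class FormatStyleError(CrowdScreenError):
    """Unknown display style passed to format_ratio."""
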
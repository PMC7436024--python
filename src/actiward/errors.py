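"""Exception hierarchy.

Every error raised on a user-facing code path derives from
:class:`ActiwardError` so callers can catch the package's failures
without swallowing programming errors.
"""


class ActiwardError(Exception):
    """Base class for all actiward errors."""


class ScheduleError(ActiwardError):
    """Posture-bout schedule is malformed (overlaps, bad durations)."""


class ConfigError(ActiwardError):
    """A configuration object or file is invalid."""


class SchemaError(ActiwardError):
    """A tabular input is missing required columns or has bad dtypes."""


class InputError(ActiwardError):
    """An operation received empty or otherwise unusable data."""


class IndexingError(ActiwardError):
    """Postoperative-day indexing is impossible (surgery date after all data)."""


class MilasValidationError(ActiwardError):
    """An assistance-scale item score is outside the 0-6 range."""


class SingularDesignError(ActiwardError):
    """Regression design matrix is rank deficient."""

    def __init__(self, message: str, collinear_terms: list[str] | None = None):
        super().__init__(message)
        self.collinear_terms = collinear_terms or []


class SeparationError(ActiwardError):
    """Logistic fit did not converge (e.g. complete separation)."""


class SingleClassError(ActiwardError):
    """Binary outcome or exposure has only one observed level."""


class SelectionError(ActiwardError):
    """Change-in-estimate selection cannot proceed (e.g. zero main effect)."""
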
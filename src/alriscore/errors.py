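"""Exception hierarchy shared across the package."""


class AlriScoreError(Exception):
    """Base class for all package errors."""


class CohortSchemaError(AlriScoreError):
    """A cohort CSV is missing a required column or a definition file is malformed."""


class RecordValueError(AlriScoreError, ValueError):
    """A field value cannot be parsed or violates an invariant.

    Carries the 1-based data row and column name when raised during CSV parsing.
    """

    def __init__(self, message: str, row: int | None = None, column: str | None = None):
        ctx = ""
        if row is not None:
            ctx += f" (row {row}"
            ctx += f", column {column!r})" if column else ")"
        elif column:
            ctx += f" (column {column!r})"
        super().__init__(message + ctx)
        self.row = row
        self.column = column


class MissingDataError(AlriScoreError):
    """A score component's required field is absent under the fail policy."""

    def __init__(self, message: str, component: str | None = None, field: str | None = None):
        super().__init__(message)
        self.component = component
        self.field = field


class UnsupportedAgeError(AlriScoreError, ValueError):
    """Age outside the range a threshold rule is defined for."""


class DegenerateInputError(AlriScoreError):
    """Outcomes contain a single class, or too few subjects for the estimator."""


class DegenerateVarianceError(AlriScoreError):
    """Paired DeLong pooled variance is zero while the AUROCs differ."""


class ZeroCellError(AlriScoreError):
    """A 2x2 table contains an empty cell and no continuity correction was requested."""


class SeparationError(AlriScoreError):
    """Complete or quasi-complete separation detected in a logistic fit."""


class RankDeficiencyError(AlriScoreError):
    """Logistic design matrix is rank deficient."""

    def __init__(self, message: str, columns: list[str] | None = None):
        super().__init__(message)
        self.columns = columns or []


class CalibrationError(AlriScoreError):
    """The generator intercept cannot be calibrated to the requested case fatality rate."""
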
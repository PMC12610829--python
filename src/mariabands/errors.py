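"""Exception hierarchy for the mariabands package."""


class MariabandsError(Exception):
    """Base class for all package-specific errors."""


class CohortValidationError(MariabandsError):
    """A cohort table violates the segment-measurement schema.

    Carries the offending row index and field name when known so that
    callers can point users at the exact cell.
    """

    def __init__(self, message, row=None, field=None):
        self.row = row
        self.field = field
        prefix = ""
        if row is not None:
            prefix += f"row {row}: "
        if field is not None:
            prefix += f"field '{field}': "
        super().__init__(prefix + message)


class MissingFieldError(MariabandsError):
    """An index was requested but the fields it needs are absent."""


class DegenerateInputError(MariabandsError):
    """Input is formally valid but statistically degenerate (e.g. zero variance)."""


class SingularCovarianceError(MariabandsError):
    """Pooled within-group covariance is singular; multivariate statistics undefined."""


class EmptyGroupError(MariabandsError):
    """A classification scheme produced an empty group where one is required."""
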
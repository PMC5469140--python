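"""Exception hierarchy."""


class InbrexError(Exception):
    """Base class for package errors."""


class DomainError(InbrexError, ValueError):
    """Input outside the mathematical domain of an operation (e.g. non-positive
    fitness passed to a log transform)."""


class DegenerateInputError(InbrexError, ValueError):
    """Structurally valid input on which the operation is undefined (zero
    variance, empty margins, no events, ...)."""


class SingularInformationError(InbrexError, ValueError):
    """The information matrix of a fit is singular, typically from collinear
    covariates.  Carries the names of the offending columns."""

    def __init__(self, columns, message=None):
        self.columns = list(columns)
        super().__init__(
            message
            or "singular information matrix; collinear covariates: "
            + ", ".join(map(str, self.columns))
        )


class NotNestedError(InbrexError, ValueError):
    """Models passed to a likelihood-ratio test are not nested."""


class MismatchedDataError(InbrexError, ValueError):
    """Two fits being compared were not computed on the same records."""
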
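"""Exception hierarchy shared across the package."""


class QsarError(Exception):
    """Base class for all qsarlab errors."""


class ParseError(QsarError, ValueError):
    """A tabular input could not be parsed or validated.

    Carries enough context (row / column / compound id) to locate the
    offending cell in the source file.
    """

    def __init__(self, message, *, row=None, column=None):
        super().__init__(message)
        self.row = row
        self.column = column


class DomainError(QsarError, ValueError):
    """An input value lies outside the mathematical domain of an operation."""


class SingularityError(QsarError, ValueError):
    """A design matrix is rank deficient or a denominator vanishes."""
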
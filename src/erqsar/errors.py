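"""Exception hierarchy shared across the package."""


class ErqsarError(Exception):
    """Base class for all package errors."""


class FixtureIntegrityError(ErqsarError):
    """The packaged study dataset failed a validation check."""


class SchemaError(ErqsarError):
    """An input table is missing required columns."""


class EmptyInputError(ErqsarError):
    """An input contained no usable rows."""


class DomainError(ErqsarError, ValueError):
    """A value is outside the mathematical domain of an operation."""


class UsageError(ErqsarError, ValueError):
    """An argument violates an operation's contract."""


class NumericError(ErqsarError):
    """An iterative numerical procedure failed to converge."""
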
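"""Exception hierarchy shared across the package.

The CLI maps these onto distinct exit codes (see :mod:`uvkin.cli`):
parse failures, validation failures and numerical failures are
distinguishable by a caller scripting around the tool.
"""


class UvkinError(Exception):
    """Base class for all package errors."""


class DomainError(UvkinError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class UsageError(UvkinError, ValueError):
    """An operation was called in a way its contract does not allow."""


class ParseError(UvkinError):
    """An input file could not be parsed into a domain object."""


class ValidationError(UvkinError):
    """A parsed or constructed object violates a domain invariant."""


class InsufficientDataError(UvkinError):
    """Too few usable observations for the requested estimate."""
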
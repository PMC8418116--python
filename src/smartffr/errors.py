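"""Exception hierarchy shared across the package."""


class SmartFFRError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(SmartFFRError, ValueError):
    """An argument violates a documented precondition."""


class FormatError(SmartFFRError, ValueError):
    """An input file is malformed.

    ``row`` is the 1-based data-row number at fault, when known.
    """

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"{message} (row {row})"
        super().__init__(message)


class UnsupportedTopologyError(SmartFFRError, ValueError):
    """The coronary-tree topology is outside what the solver handles."""


class OutOfDomainError(SmartFFRError, ValueError):
    """A closed-form shortcut was requested outside its validity domain."""
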
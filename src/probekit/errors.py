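"""Exception hierarchy.

Every error raised by the library derives from :class:`ProbekitError`, so
callers (and the CLI) can catch one base class.  Parsing errors carry enough
context (line/position numbers) to point a user at the offending input.
"""


class ProbekitError(Exception):
    """Base class for all errors raised by probekit."""


class InvalidSequenceError(ProbekitError):
    """Sequence contains a character outside {A, C, G, U, T} (any case)."""

    def __init__(self, message: str, position: int | None = None):
        super().__init__(message)
        self.position = position


class FormatError(ProbekitError):
    """A structured input file violates its format contract."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message)
        self.line = line


class ReconciliationError(ProbekitError):
    """Two representations of the same molecule disagree."""

    def __init__(self, message: str, report=None):
        super().__init__(message)
        self.report = report


class StateError(ProbekitError):
    """Operation applied to a profile in the wrong normalization state."""


class EmptyRoiError(ProbekitError):
    """Region-of-interest trimming removed every position."""


class TooFewValuesError(ProbekitError):
    """Not enough measured values to apply the 2-8% normalization rule."""


class NonPositiveFactorError(ProbekitError):
    """The normalization divisor would be zero or negative."""


class DotBracketError(ProbekitError):
    """Dot-bracket text is unbalanced or contains an illegal character."""

    def __init__(self, message: str, position: int | None = None, family: str | None = None):
        super().__init__(message)
        self.position = position
        self.family = family


class CapacityError(ProbekitError):
    """More bracket families are needed than the notation provides."""


class InputCountError(ProbekitError):
    """An operation needs more inputs than were supplied."""


class ConfigurationError(ProbekitError):
    """A run configuration is internally inconsistent or names an unknown mode."""


class ChainNotFoundError(ProbekitError):
    """The requested chain does not occur in the PDB file."""


class LengthError(ProbekitError):
    """Input sequence exceeds the configured maximum length."""
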
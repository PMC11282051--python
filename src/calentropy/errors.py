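"""Exception hierarchy.

All package-specific failures derive from :class:`CalentropyError` so callers
(and the CLI) can distinguish validation problems (exit code 2) from bugs.
"""


class CalentropyError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(CalentropyError):
    """A text input could not be parsed; the message names the offending line."""


class ValidationError(CalentropyError):
    """Data violate a structural invariant (shape, sign, contiguity, missing cells)."""


class CoverageError(CalentropyError):
    """A cohort diagonal or CAL computation needs Lexis cells the surface lacks."""


class DomainError(CalentropyError):
    """A mathematical precondition fails (non-positive value, degenerate input)."""


class ConstructionError(CalentropyError):
    """A synthetic construction failed its own internal verification."""
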
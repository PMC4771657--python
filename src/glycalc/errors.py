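"""Exception hierarchy.

Everything raised on bad user input derives from :class:`GlycalcError`
so the CLI can catch one type and exit non-zero with a one-line message.
"""


class GlycalcError(Exception):
    """Base class for all glycalc errors."""


class UnitError(GlycalcError, ValueError):
    """Unknown or incompatible glucose unit label."""


class DomainError(GlycalcError, ValueError):
    """Physically meaningless input (negative glucose, HbA1c below the
    zero-glucose crossing, cell age outside the trajectory coverage)."""


class ConfigurationError(GlycalcError, ValueError):
    """Inconsistent configuration: profile/scheme length mismatch,
    weights not summing to 1, unknown model or scheme name."""


class CoverageError(GlycalcError, ValueError):
    """A required time window or life span is not covered by the data."""


class FormatError(GlycalcError, ValueError):
    """Malformed input file (missing column, bad header)."""


class ValidationError(GlycalcError, ValueError):
    """Well-formed file with invalid content (non-positive values,
    unparseable timestamps); the message names the offending rows."""


class NumericalError(GlycalcError, ArithmeticError):
    """A numerical procedure degenerated (e.g. zero sensitivity in a
    finite-difference weight computation)."""
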
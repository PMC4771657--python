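"""Display rounding: round-half-away-from-zero, as clinical tables print.

Internal computation is never rounded; these helpers are applied only when
rendering a value for a human-facing table (2 decimals for HbA1c percent,
integers for glucose in mg/dl). Python's built-in ``round`` is banker's
rounding and would print 8.485 as 8.48, not the conventional 8.49.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round ties away from zero (0.5 -> 1, -0.5 -> -1)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def display_percent(x: float) -> float:
    """HbA1c percent as printed: 2 decimal places."""
    return round_half_away(x, 2)


def display_mgdl(x: float) -> float:
    """Glucose in mg/dl as printed: nearest integer."""
    return round_half_away(x, 0)
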
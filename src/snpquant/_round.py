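"""Decimal rounding helpers (half away from zero, the convention used for reporting)."""

from decimal import Decimal, ROUND_HALF_UP


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round ``x`` to ``ndigits`` decimals, ties going away from zero.

    Python's built-in ``round`` uses banker's rounding; reported lengths,
    densities, doses and percentages here follow the half-away-from-zero
    convention instead.  Goes through the shortest decimal repr so that
    values like 9.8625 round up to 9.863 rather than falling victim to
    binary representation error.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(x)).quantize(q, rounding=ROUND_HALF_UP))


def round_half_away_int(x: float) -> int:
    """Round to the nearest integer, ties away from zero."""
    return int(round_half_away(x, 0))
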
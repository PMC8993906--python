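"""Printed-summary formatting helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def format_percent(numerator, denominator, decimals: int = 0) -> str:
    """Render ``100 * numerator / denominator`` as a printed percentage.

    Rounds half away from zero (so 58.95 -> "59.0", not banker's
    rounding) and renders without a decimal point when ``decimals`` is 0,
    matching the ratio convention of cohort summaries like
    "59% (1622/2751)".
    """
    if denominator == 0:
        raise ZeroDivisionError("format_percent denominator must be nonzero")
    if decimals < 0:
        raise ValueError("decimals must be >= 0")
    value = Decimal(100) * Decimal(str(numerator)) / Decimal(str(denominator))
    quantum = Decimal(1).scaleb(-decimals)
    rounded = value.quantize(quantum, rounding=ROUND_HALF_UP)
    if decimals == 0:
        return f"{int(rounded)}%"
    return f"{rounded}%"


def percent_value(numerator, denominator, decimals: int = 0) -> float:
    """The numeric value behind :func:`format_percent` (e.g. 58.2)."""
    return float(format_percent(numerator, denominator, decimals).rstrip("%"))
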
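"""Decimal presentation helpers.

Reported percentages are rounded half-up to one decimal (the convention of
the French hospital-coding literature this package serves); a truncating
variant exists because published precision figures are occasionally
truncated toward zero instead.
"""

from decimal import ROUND_DOWN, ROUND_HALF_UP, Decimal

__all__ = ["round1", "trunc1", "pct"]


def round1(x: float) -> float:
    """Round to one decimal, half away from zero (round-half-up)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def trunc1(x: float) -> float:
    """Truncate toward zero at one decimal."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_DOWN))


def pct(numerator: float, denominator: float) -> float:
    """Unrounded percentage 100*numerator/denominator."""
    return 100.0 * numerator / denominator
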
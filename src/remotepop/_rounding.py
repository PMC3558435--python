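"""Rounding helpers.

All integer reporting in this package rounds halves away from zero
(so 1440.5 -> 1441 and -12057.5 -> -12058), never to even. Decimal
reporting (one-decimal percents and occupancies) follows the same rule.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_away(x: float) -> int:
    """Round to the nearest integer, ties away from zero."""
    return int(Decimal(repr(float(x))).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def round_to_decimals(x: float, ndigits: int = 1) -> float:
    """Round to `ndigits` decimals, ties away from zero."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
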
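"""Money arithmetic in integer cents.

All monetary fields are stored internally as integer US cents so that sums
are associative and CSV round-trips are bit-exact. Rendering is always USD
with two decimals.
"""
from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP


def to_cents(value: float | int | str | Decimal) -> int:
    """Parse a USD amount into integer cents, rounding half-up at the cent."""
    d = Decimal(str(value))
    return int(d.scaleb(2).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def cents_to_usd(cents: int) -> float:
    return cents / 100.0


def format_usd(cents: int) -> str:
    sign = "-" if cents < 0 else ""
    cents = abs(cents)
    return f"{sign}{cents // 100}.{cents % 100:02d}"


def round_half_up(x: float) -> int:
    """Round to nearest integer, ties away from zero (half-up for x >= 0)."""
    return int(Decimal(str(x)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))
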
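"""Display-rounding helpers.

All money and fractions are carried at full double precision internally;
rounding happens only when a value is displayed or, in paper-rounding
mode, at the two documented chain points (the reduction fraction and the
uptake increase). Half-way cases round away from zero ("half-up"), which
is deterministic across platforms, unlike banker's rounding.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round ``value`` to ``ndigits`` decimals, ties away from zero.

    ``round_half_up(26373.5) == 26374.0`` whereas the built-in ``round``
    would give 26374 only by accident of binary representation.
    """
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def fraction_to_points(fraction: float) -> float:
    """Convert a 0-1 fraction to percentage points (0.217 -> 21.7)."""
    return fraction * 100.0


def points_to_fraction(points: float) -> float:
    """Convert percentage points to a 0-1 fraction (21.7 -> 0.217)."""
    return points / 100.0
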
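"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties going away from zero, as report tables conventionally do.

    Python's built-in ``round`` is banker's rounding; safety-report tables are
    printed with half-up rounding, so 0.125 → 0.13 at 2 dp.
    """
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
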
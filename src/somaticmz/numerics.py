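"""Small numeric helpers shared across modules."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero, as printed summary percentages do.

    Python's built-in ``round`` uses banker's rounding (ties to even), which
    does not reproduce display values like 12.5 % → "13 %". Operates on the
    decimal repr of ``x`` to avoid binary-float tie artifacts.
    """
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))
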
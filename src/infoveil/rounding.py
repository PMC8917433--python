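"""Percentage arithmetic with explicit round-half-up semantics.

Report tables round percentages half-up (5 rounds away from zero), which is
what published tables conventionally print; Python's built-in ``round`` is
banker's rounding and disagrees on exact halves. Division is done in
``decimal`` so ties are genuine ties, not float artifacts.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def percent(count: int, total: int, decimals: int = 1) -> float:
    """Return ``100 * count / total`` rounded half-up to ``decimals`` places.

    A zero total yields 0.0 so degenerate (empty) strata render cleanly.
    """
    if total == 0:
        return 0.0
    quantum = Decimal(1).scaleb(-decimals)
    value = (Decimal(count) * 100 / Decimal(total)).quantize(quantum, ROUND_HALF_UP)
    return float(value)
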
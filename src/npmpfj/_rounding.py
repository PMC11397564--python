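"""Decimal rounding helpers.

The band-start arithmetic is defined on printed decimal values, so rounding
must behave like pencil-and-paper half-up rounding, not binary float
rounding (e.g. 82.5 rounds to 83, where Python's built-in round gives 82).
"""

from decimal import Decimal, ROUND_HALF_UP


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round ``value`` half away from zero at ``ndigits`` decimal places."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP))
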
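"""Half-up decimal rounding used for all table-style reporting.

Python's built-in ``round`` is banker's rounding (62.745 -> 62.74); composition
tables in the food-science literature round half away from zero (-> 62.75), so
every reported value in this package goes through :func:`round_half_up`.
"""

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up"]


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round ``value`` to ``ndigits`` decimals, ties away from zero.

    The value is routed through ``repr`` so that the decimal being rounded is
    the shortest decimal representation of the float, which is what a human
    (or a spreadsheet) would round.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
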
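"""Display rounding used throughout the reports.

All reported statistics carry both the raw float and the display string the
tables print. Rounding is nearest, half away from zero (not banker's), so
e.g. 29.5 displays as 30.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import NamedTuple


class Stat(NamedTuple):
    """A statistic with its raw value and the table display string."""

    value: float
    display: str


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round to ``ndigits`` decimals, ties away from zero."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def display(x: float, ndigits: int = 0) -> str:
    """Format ``x`` with ``ndigits`` decimals, ties away from zero."""
    v = round_half_away(x, ndigits)
    if ndigits == 0:
        return str(int(v))
    return f"{v:.{ndigits}f}"
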
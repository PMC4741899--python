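"""Half-up decimal rounding and exact 4-decimal sums for reported values.

Reported RMSD values are fixed-point with 4 decimals; totals are sums of
those fixed-point components, so they must be computed without binary
floating drift.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable

__all__ = ["round_half_up", "format4", "sum4"]


def round_half_up(value: float, ndigits: int = 4) -> float:
    """Round with ties away from zero at ``ndigits`` decimals (91.665 -> 91.67)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def format4(value: float) -> str:
    """Canonical 4-decimal rendering used in TSV serialisations."""
    return f"{round_half_up(value, 4):.4f}"


def sum4(values: Iterable[float]) -> float:
    """Exact sum of values that are 4-decimal fixed-point numbers."""
    total = sum((Decimal(format4(v)) for v in values), Decimal("0.0000"))
    return float(total)
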
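"""Small shared numeric helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, decimals: int = 2) -> float:
    """Round with ties going away from zero, as in printed atlas tables.

    Python's built-in ``round`` uses banker's rounding, which disagrees with
    the half-up convention of published percentage tables (e.g. 1.435 -> 1.44).
    """
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def percent(count: float, total: float, decimals: int = 2) -> float:
    """``count / total`` as a half-up-rounded percentage; 0.0 for empty totals."""
    if total == 0:
        return 0.0
    return round_half_up(100.0 * count / total, decimals)
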
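"""Small numeric helpers shared across modules."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence, Tuple


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (half-up), as printed tables do.

    Python's builtin ``round`` uses banker's rounding; reported percentages
    and mean lengths follow the half-up convention instead.
    """
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))


def interval_union_length(intervals: Iterable[Tuple[int, int]]) -> int:
    """Total number of integer positions covered by 1-based inclusive intervals.

    Endpoints given in either order are normalised; overlapping and adjacent
    intervals are merged before counting.
    """
    normalised = sorted((lo, hi) if lo <= hi else (hi, lo) for lo, hi in intervals)
    total = 0
    cur_lo = cur_hi = None
    for lo, hi in normalised:
        if cur_lo is None:
            cur_lo, cur_hi = lo, hi
        elif lo <= cur_hi + 1:
            cur_hi = max(cur_hi, hi)
        else:
            total += cur_hi - cur_lo + 1
            cur_lo, cur_hi = lo, hi
    if cur_lo is not None:
        total += cur_hi - cur_lo + 1
    return total


def covered_length_within(
    intervals: Sequence[Tuple[int, int]], lo: int, hi: int
) -> int:
    """Positions of [lo, hi] (1-based inclusive) covered by the intervals."""
    clipped = [
        (max(a, lo), min(b, hi))
        for a, b in intervals
        if not (b < lo or a > hi)
    ]
    return interval_union_length(clipped)
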
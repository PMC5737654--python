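"""Transcriptome summary statistics: GC%, N50, length summary, length bins."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, List, NamedTuple, Sequence

import numpy as np
import pandas as pd

from ._util import round_half_up
from .seqio import TranscriptRecord

__all__ = [
    "SummaryStats",
    "Histogram",
    "gc_content",
    "n50",
    "summarize",
    "length_histogram",
    "log_bin_edges",
]

#: Column order of the standard per-dataset summary row.
SUMMARY_COLUMNS = (
    "gc_percent",
    "n50",
    "mean_length",
    "min_length",
    "max_length",
    "n_sequences",
)


@dataclass(frozen=True)
class SummaryStats:
    """One-row dataset summary in the conventional report order."""

    n_sequences: int
    gc_percent: float
    n50: int
    mean_length: int
    min_length: int
    max_length: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{c: getattr(self, c) for c in SUMMARY_COLUMNS}])


def gc_content(records: Iterable[TranscriptRecord]) -> float:
    """Pooled GC percentage over all records, 1 decimal (half-up).

    Ambiguity codes are excluded from both numerator and denominator, so
    only unambiguous A/C/G/T bases count. Pooling (rather than averaging
    per-sequence GC) makes the result invariant to how the same bases are
    split across records.
    """
    gc = 0
    acgt = 0
    for rec in records:
        seq = rec.seq
        gc += seq.count("G") + seq.count("C")
        acgt += seq.count("A") + seq.count("T") + seq.count("G") + seq.count("C")
    if acgt == 0:
        raise ValueError("cannot compute GC content: no unambiguous bases")
    return round_half_up(100.0 * gc / acgt, 1)


def n50(lengths: Sequence[int]) -> int:
    """Standard N50: smallest L with total bases in sequences >= L at least
    half the total. Computed by descending cumulative sum; at a tie the
    length where the cumulative sum first reaches half is returned."""
    if len(lengths) == 0:
        raise ValueError("N50 of an empty length list is undefined")
    arr = np.sort(np.asarray(lengths, dtype=np.int64))[::-1]
    total = int(arr.sum())
    csum = np.cumsum(arr)
    idx = int(np.searchsorted(2 * csum, total, side="left"))
    return int(arr[idx])


def summarize(records: Sequence[TranscriptRecord]) -> SummaryStats:
    """All dataset summary fields at once; mean rounded half-up to integer."""
    if not records:
        raise ValueError("cannot summarize an empty record set")
    lengths = [r.length for r in records]
    return SummaryStats(
        n_sequences=len(records),
        gc_percent=gc_content(records),
        n50=n50(lengths),
        mean_length=int(round_half_up(sum(lengths) / len(lengths), 0)),
        min_length=min(lengths),
        max_length=max(lengths),
    )


class Histogram(NamedTuple):
    edges: List[float]
    counts: List[int]
    overflow: int


def log_bin_edges(lo: float, hi: float, n_bins: int) -> List[float]:
    """Logarithmically spaced bin edges, as used for transcript length
    distributions spanning two orders of magnitude."""
    if lo <= 0 or hi <= lo or n_bins < 1:
        raise ValueError("need 0 < lo < hi and n_bins >= 1")
    return list(np.geomspace(lo, hi, n_bins + 1))


def length_histogram(lengths: Sequence[int], edges: Sequence[float]) -> Histogram:
    """Bin lengths into half-open bins [edges[i], edges[i+1]).

    A length equal to an inner edge goes into the bin that edge opens.
    Lengths outside all bins are counted in ``overflow`` with a warning.
    Bin counts plus overflow always sum to ``len(lengths)``.
    """
    edges_arr = np.asarray(edges, dtype=float)
    if edges_arr.ndim != 1 or len(edges_arr) < 2:
        raise ValueError("need at least two bin edges")
    if not np.all(np.diff(edges_arr) > 0):
        raise ValueError("bin edges must be strictly increasing")
    counts = [0] * (len(edges_arr) - 1)
    overflow = 0
    for x in lengths:
        if x < edges_arr[0] or x >= edges_arr[-1]:
            overflow += 1
            continue
        idx = int(np.searchsorted(edges_arr, x, side="right")) - 1
        counts[idx] += 1
    if overflow:
        warnings.warn(
            f"{overflow} length(s) fell outside the bin range and were "
            "counted in the overflow bin",
            stacklevel=2,
        )
    return Histogram(edges=list(edges_arr), counts=counts, overflow=overflow)
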
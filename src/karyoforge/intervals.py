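"""Low-level interval arithmetic on 0-based half-open coordinates.

Every genomic coordinate in this package is 0-based, half-open
(``start`` inclusive, ``end`` exclusive).  Conversion to 1-based inclusive
coordinates happens only at export boundaries (AGP, human-readable reports).
Interval tracks are represented as ``(n, 2)`` integer numpy arrays sorted by
start with overlaps merged, which makes coverage queries a pair of binary
searches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "SeqInterval",
    "as_interval_array",
    "merge_intervals",
    "covered_bases",
    "coverage_in_windows",
    "total_length",
]


@dataclass(frozen=True)
class SeqInterval:
    """A half-open interval on a named chromosome.

    strand is '+', '-' or None (unoriented).
    """

    chrom: str
    start: int
    end: int
    strand: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in (None, "+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "SeqInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "SeqInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


def as_interval_array(intervals: Iterable[Sequence[int]]) -> np.ndarray:
    """Coerce an iterable of (start, end) pairs to an (n, 2) int64 array."""
    arr = np.asarray(list(intervals), dtype=np.int64)
    if arr.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("expected (start, end) pairs")
    if np.any(arr[:, 0] >= arr[:, 1]):
        raise ValueError("intervals must satisfy start < end")
    if np.any(arr[:, 0] < 0):
        raise ValueError("negative coordinates")
    return arr


def merge_intervals(arr: np.ndarray) -> np.ndarray:
    """Sort by start and merge overlapping or bookended intervals.

    Duplicates collapse; the result is the minimal sorted disjoint cover.
    """
    arr = as_interval_array(arr)
    if len(arr) == 0:
        return arr
    order = np.argsort(arr[:, 0], kind="stable")
    arr = arr[order]
    merged = [list(arr[0])]
    for s, e in arr[1:]:
        if s <= merged[-1][1]:
            if e > merged[-1][1]:
                merged[-1][1] = e
        else:
            merged.append([s, e])
    return np.asarray(merged, dtype=np.int64)


def _cum_coverage_at(merged: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Covered bases in [0, x) for each x, given a merged interval array."""
    if len(merged) == 0:
        return np.zeros(len(x), dtype=np.int64)
    starts = merged[:, 0]
    ends = merged[:, 1]
    cum = np.concatenate([[0], np.cumsum(ends - starts)])
    x = np.asarray(x, dtype=np.int64)
    # intervals 0..i-1 start before x; the last of them may be partially cut
    i = np.searchsorted(starts, x, side="left")
    out = np.zeros(len(x), dtype=np.int64)
    mask = i > 0
    if np.any(mask):
        prev = i[mask] - 1
        partial = np.clip(np.minimum(x[mask], ends[prev]) - starts[prev], 0, None)
        out[mask] = cum[prev] + partial
    return out


def covered_bases(merged: np.ndarray, start: int, end: int) -> int:
    """Bases of [start, end) covered by a merged interval array."""
    if end <= start:
        raise ValueError("zero- or negative-length query window")
    lo, hi = _cum_coverage_at(merged, np.asarray([start, end], dtype=np.int64))
    return int(hi - lo)


def coverage_in_windows(merged: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Covered bases within each window defined by consecutive ``edges``.

    ``edges`` is a sorted 1-D array of window boundaries; returns an array of
    length ``len(edges) - 1``.
    """
    edges = np.asarray(edges, dtype=np.int64)
    cum = _cum_coverage_at(merged, edges)
    return np.diff(cum)


def total_length(merged: np.ndarray) -> int:
    if len(merged) == 0:
        return 0
    return int(np.sum(merged[:, 1] - merged[:, 0]))
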
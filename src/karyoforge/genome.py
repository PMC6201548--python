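"""Genome container, density primitives, and shared assembly statistics.

A :class:`Genome` is coordinate-only: an ordered map of chromosome lengths
plus named interval tracks (typically ``"CNE"``, ``"msHSB"`` and an optional
``"gap"`` track marking bases with no sequence data).  Tracks are normalized
on load: intervals sorted, clipped against the chromosome, overlaps merged —
so per-window densities are well defined regardless of input interval order.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional

import numpy as np

from .intervals import (
    SeqInterval,
    as_interval_array,
    covered_bases,
    coverage_in_windows,
    merge_intervals,
    total_length,
)

__all__ = [
    "Genome",
    "AssemblyStats",
    "compute_n50",
    "cne_fraction",
    "percent_of_assembly",
    "round_half_even",
    "read_bed3",
    "write_bed3",
    "read_genome_tsv",
    "write_genome_tsv",
]

GAP_TRACK = "gap"


class Genome:
    """Chromosome lengths plus named, normalized interval tracks."""

    def __init__(
        self,
        chromosomes: Mapping[str, int],
        tracks: Optional[Mapping[str, Mapping[str, np.ndarray]]] = None,
    ) -> None:
        self.chromosomes: Dict[str, int] = {}
        for chrom, length in chromosomes.items():
            length = int(length)
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length")
            self.chromosomes[str(chrom)] = length
        self.tracks: Dict[str, Dict[str, np.ndarray]] = {}
        if tracks:
            for name, per_chrom in tracks.items():
                for chrom, arr in per_chrom.items():
                    self.add_track_intervals(name, chrom, arr)

    # -- track management -------------------------------------------------

    def add_track_intervals(self, name, chrom, intervals) -> None:
        """Add intervals to a track on one chromosome (merged, clipped)."""
        if chrom not in self.chromosomes:
            raise KeyError(f"unknown chromosome {chrom!r}")
        arr = as_interval_array(intervals)
        if len(arr) and int(arr[:, 1].max()) > self.chromosomes[chrom]:
            raise ValueError(
                f"track {name!r} interval exceeds length of chromosome {chrom}"
            )
        track = self.tracks.setdefault(name, {})
        if chrom in track and len(track[chrom]):
            arr = np.vstack([track[chrom], arr]) if len(arr) else track[chrom]
        track[chrom] = merge_intervals(arr) if len(arr) else as_interval_array([])

    def set_track(self, name: str, per_chrom: Mapping[str, Iterable]) -> None:
        self.tracks[name] = {}
        for chrom, ivs in per_chrom.items():
            self.add_track_intervals(name, chrom, ivs)

    def track(self, name: str, chrom: str) -> np.ndarray:
        return self.tracks.get(name, {}).get(chrom, as_interval_array([]))

    def track_total(self, name: str) -> int:
        return sum(total_length(a) for a in self.tracks.get(name, {}).values())

    # -- basic quantities --------------------------------------------------

    @property
    def total_length(self) -> int:
        return sum(self.chromosomes.values())

    def track_density(self, name: str) -> float:
        return self.track_total(name) / self.total_length

    def window_edges(self, chrom: str, window: int = 1000) -> np.ndarray:
        """Edges of non-overlapping windows tiled from 0.

        The final partial window is dropped (its right edge is not emitted).
        """
        length = self.chromosomes[chrom]
        n = length // window
        return np.arange(n + 1, dtype=np.int64) * window

    def window_track_bases(
        self, name: str, chrom: str, window: int = 1000
    ) -> np.ndarray:
        """Track-covered bases in each full window of ``chrom``."""
        edges = self.window_edges(chrom, window)
        return coverage_in_windows(self.track(name, chrom), edges)

    def check_interval(self, iv: SeqInterval) -> None:
        if iv.chrom not in self.chromosomes:
            raise KeyError(f"unknown chromosome {iv.chrom!r}")
        if iv.end > self.chromosomes[iv.chrom]:
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome length"
            )

    def copy(self) -> "Genome":
        g = Genome(dict(self.chromosomes))
        for name, per_chrom in self.tracks.items():
            g.tracks[name] = {c: a.copy() for c, a in per_chrom.items()}
        return g


@dataclass
class AssemblyStats:
    """Summary statistics for a set of assembly units.

    Percentages are of the original (input) assembly length; invariant
    0 <= pct_oriented <= pct_placed <= 100.
    """

    n_units: int
    total_length: int
    n50: int
    pct_placed: float = 100.0
    pct_oriented: float = 100.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.pct_oriented <= self.pct_placed <= 100.0 + 1e-9):
            raise ValueError(
                "need 0 <= pct_oriented <= pct_placed <= 100 "
                f"(got {self.pct_oriented}, {self.pct_placed})"
            )


def compute_n50(lengths: Iterable[int]) -> int:
    """N50: the length L such that units >= L hold at least half the total.

    Computed by scanning lengths in decreasing order until the running sum
    reaches half of the grand total.
    """
    lens = sorted(int(x) for x in lengths)
    if not lens:
        raise ValueError("compute_n50: empty length multiset")
    if lens[0] <= 0:
        raise ValueError("compute_n50: lengths must be positive")
    lens.reverse()
    half = sum(lens) / 2.0
    acc = 0
    for L in lens:
        acc += L
        if acc >= half:
            return L
    raise AssertionError("unreachable")


def cne_fraction(window: SeqInterval, track: np.ndarray) -> float:
    """Fraction of a window's bases covered by a (merged) interval track."""
    if window.length <= 0:
        raise ValueError("zero-length window")
    return covered_bases(track, window.start, window.end) / window.length


def percent_of_assembly(part_length: int, original_length: int) -> float:
    """100 * part/original, full precision (round only for display)."""
    if original_length <= 0:
        raise ValueError("original assembly length must be positive")
    if not (0 <= part_length <= original_length):
        raise ValueError("part length must lie in [0, original]")
    return 100.0 * part_length / original_length


def round_half_even(x: float, ndigits: int = 2) -> float:
    """Banker's rounding used for all reported percentages."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_EVEN))


# -- plain-text external formats ------------------------------------------


def read_bed3(path) -> Dict[str, np.ndarray]:
    """Read a BED3 file into per-chromosome merged interval arrays.

    ``browser``/``track`` and comment lines are skipped; coordinates are
    0-based half-open as in BED.
    """
    per_chrom: Dict[str, list] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "browser", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                parts = line.split()
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            per_chrom.setdefault(chrom, []).append((start, end))
    return {c: merge_intervals(as_interval_array(v)) for c, v in per_chrom.items()}


def write_bed3(path, per_chrom: Mapping[str, np.ndarray]) -> None:
    with open(path, "w") as fh:
        for chrom in per_chrom:
            for s, e in np.asarray(per_chrom[chrom], dtype=np.int64):
                fh.write(f"{chrom}\t{int(s)}\t{int(e)}\n")


def read_genome_tsv(path) -> Dict[str, int]:
    """Two-column TSV ``chrom<TAB>length``."""
    chroms: Dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, length = line.split("\t")[:2]
            chroms[chrom] = int(length)
    return chroms


def write_genome_tsv(path, chromosomes: Mapping[str, int]) -> None:
    with open(path, "w") as fh:
        for chrom, length in chromosomes.items():
            fh.write(f"{chrom}\t{int(length)}\n")
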
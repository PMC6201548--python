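"""CNE density statistics around breakpoint regions.

Implements the density contrasts used to test whether conserved non-coding
elements are depleted where chromosome rearrangements are fixed:

* per-EBR flank contrast — each EBR (extended by 1 kb when shorter than
  1 kb) is compared with two upstream and two downstream abutting windows of
  its own size;
* a genome-wide scan of 1-kb non-overlapping windows classified as
  msHSB / fusion-EBR / fission-EBR / intrachromosomal-EBR / rest, with
  per-class mean CNE bases and densities;
* the distance (in windows) from each zero-CNE window to the nearest window
  at or above the msHSB average density;
* rank-based tests: Kruskal-Wallis and Mann-Whitney U with an exact
  enumeration path for small samples and a tie- and continuity-corrected
  normal approximation otherwise.

No multiple-testing correction is applied; reports flag this.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome import Genome
from .intervals import SeqInterval, as_interval_array, coverage_in_windows, merge_intervals
from .homology import EBR

__all__ = [
    "FlankSet",
    "DensityReport",
    "WindowScanResult",
    "make_flank_set",
    "ebr_flank_contrast",
    "scan_1kb_windows",
    "distance_to_mshsb_density",
    "mann_whitney_u",
    "kruskal_wallis",
]

EXTEND_BELOW = 1_000
EXTEND_BY = 1_000
EXACT_LIMIT = 12  # exact MWU enumeration up to this pooled sample size

WINDOW_CLASSES = ("msHSB", "fusion", "fission", "intrachromosomal", "rest")


@dataclass
class FlankSet:
    """An (extended) EBR with its four same-size abutting flank windows.

    Window keys are -2, -1 (upstream) and +1, +2 (downstream); a window
    clipped at a chromosome end is flagged truncated (and absent if fully
    clipped away).
    """

    ebr: SeqInterval
    windows: Dict[int, Optional[SeqInterval]]
    truncated: frozenset


def make_flank_set(ebr: SeqInterval, genome: Genome) -> FlankSet:
    genome.check_interval(ebr)
    start, end = ebr.start, ebr.end
    if end - start < EXTEND_BELOW:
        start = max(start - EXTEND_BY, 0)
        end = min(end + EXTEND_BY, genome.chromosomes[ebr.chrom])
    ext = SeqInterval(ebr.chrom, start, end)
    L = ext.length
    chrom_len = genome.chromosomes[ebr.chrom]
    raw = {
        -2: (start - 2 * L, start - L),
        -1: (start - L, start),
        +1: (end, end + L),
        +2: (end + L, end + 2 * L),
    }
    windows: Dict[int, Optional[SeqInterval]] = {}
    truncated = set()
    for key, (s, e) in raw.items():
        cs, ce = max(s, 0), min(e, chrom_len)
        if cs >= ce:
            windows[key] = None
            truncated.add(key)
        else:
            windows[key] = SeqInterval(ebr.chrom, cs, ce)
            if (cs, ce) != (s, e):
                truncated.add(key)
    return FlankSet(ebr=ext, windows=windows, truncated=frozenset(truncated))


@dataclass
class DensityReport:
    """Per-group CNE densities with rank-test results."""

    group_values: Dict[str, List[float]]
    group_means: Dict[str, float]
    kruskal: Tuple[float, float]
    mannwhitney: Tuple[float, float]
    n_ebrs: int
    notes: str = "no multiple-testing correction applied"


def _density(genome: Genome, iv: SeqInterval, track: str) -> float:
    arr = genome.track(track, iv.chrom)
    return float(
        coverage_in_windows(arr, np.asarray([iv.start, iv.end]))[0] / iv.length
    )


def ebr_flank_contrast(
    ebrs: Sequence[EBR],
    genome: Genome,
    cne_track: str = "CNE",
    max_len: int = 100_000,
    alternative: str = "two-sided",
    min_ebrs: int = 2,
) -> DensityReport:
    """Compare CNE fractions of EBRs with their flanking windows.

    Only EBRs at most ``max_len`` long enter the analysis.  Kruskal-Wallis
    runs across the five positional groups; Mann-Whitney U compares EBR
    densities with the pooled flanks.
    """
    ebr_vals: List[float] = []
    flank_vals: Dict[int, List[float]] = {-2: [], -1: [], 1: [], 2: []}
    used = 0
    for e in ebrs:
        if e.excluded_from_cne or e.length > max_len:
            continue
        if e.unit not in genome.chromosomes:
            raise KeyError(f"EBR on unknown chromosome {e.unit!r}")
        fs = make_flank_set(SeqInterval(e.unit, e.start, e.end), genome)
        usable = [k for k, w in fs.windows.items() if w is not None and k not in fs.truncated]
        if not usable:
            continue
        used += 1
        ebr_vals.append(_density(genome, fs.ebr, cne_track))
        for k in usable:
            flank_vals[k].append(_density(genome, fs.windows[k], cne_track))
    if used < min_ebrs:
        raise ValueError(
            f"need at least {min_ebrs} EBRs with untruncated flanks (got {used})"
        )
    groups = {"EBR": ebr_vals}
    for k in (-2, -1, 1, 2):
        groups[f"flank{k:+d}"] = flank_vals[k]
    pooled_flanks = [v for k in (-2, -1, 1, 2) for v in flank_vals[k]]
    kw = kruskal_wallis([g for g in groups.values() if g])
    mw = mann_whitney_u(ebr_vals, pooled_flanks, alternative=alternative)
    return DensityReport(
        group_values=groups,
        group_means={k: (float(np.mean(v)) if v else float("nan")) for k, v in groups.items()},
        kruskal=kw,
        mannwhitney=mw,
        n_ebrs=used,
    )


# ---------------------------------------------------------------------------
# genome-wide 1-kb window scan


@dataclass
class WindowScanResult:
    table: pd.DataFrame  # chrom, start, cne_bases, cls, usable
    class_mean_bases: Dict[str, float]
    class_mean_density: Dict[str, float]
    genome_mean_bases: float
    genome_mean_density: float
    window_size: int = 1000


def scan_1kb_windows(
    genome: Genome,
    ebrs: Sequence[EBR],
    window: int = 1000,
    excluded_chroms: Sequence[str] = (),
    cne_track: str = "CNE",
    mshsb_track: str = "msHSB",
    gap_track: str = "gap",
    mshsb_min_len: int = 1_500_000,
    min_sequenced_frac: float = 0.5,
) -> WindowScanResult:
    """Tile chromosomes into non-overlapping windows and classify each.

    Tiling starts at 0 and the final partial window is dropped.  Windows
    with at most ``min_sequenced_frac`` of sequenced bases (per the gap
    track; everything is sequenced without one) are unusable.  A window
    overlapping any part of a (non-excluded) EBR takes that EBR's class;
    otherwise msHSB blocks above ``mshsb_min_len`` claim it; the remainder
    is 'rest'.  Class precedence: EBR classes > msHSB > rest, and among EBR
    classes the largest overlap wins (ties: fission > fusion >
    intrachromosomal).
    """
    ebr_by_class_chrom: Dict[str, Dict[str, List[Tuple[int, int]]]] = {
        "fission": {}, "fusion": {}, "intrachromosomal": {}
    }
    for e in ebrs:
        if e.excluded_from_cne or e.length > 100_000:
            continue
        ebr_by_class_chrom[e.cls].setdefault(e.unit, []).append((e.start, e.end))

    rows = []
    for chrom, length in genome.chromosomes.items():
        if chrom in excluded_chroms:
            continue
        edges = genome.window_edges(chrom, window)
        if len(edges) < 2:
            continue
        n = len(edges) - 1
        cne_bases = coverage_in_windows(genome.track(cne_track, chrom), edges)
        if gap_track in genome.tracks:
            gap_bases = coverage_in_windows(genome.track(gap_track, chrom), edges)
        else:
            gap_bases = np.zeros(n, dtype=np.int64)
        usable = (window - gap_bases) > min_sequenced_frac * window

        overlaps = {}
        for cls in ("fission", "fusion", "intrachromosomal"):
            ivs = ebr_by_class_chrom[cls].get(chrom, [])
            if ivs:
                merged = merge_intervals(
                    as_interval_array([(max(0, s), min(e, length)) for s, e in ivs])
                )
                overlaps[cls] = coverage_in_windows(merged, edges)
            else:
                overlaps[cls] = np.zeros(n, dtype=np.int64)
        hsb_arr = np.asarray(genome.track(mshsb_track, chrom), dtype=np.int64)
        if len(hsb_arr):
            hsb_arr = hsb_arr[(hsb_arr[:, 1] - hsb_arr[:, 0]) > mshsb_min_len]
        hsb = (
            coverage_in_windows(hsb_arr, edges)
            if len(hsb_arr)
            else np.zeros(n, dtype=np.int64)
        )

        cls_arr = np.full(n, "rest", dtype=object)
        ebr_stack = np.stack(
            [overlaps["fission"], overlaps["fusion"], overlaps["intrachromosomal"]]
        )
        has_ebr = ebr_stack.sum(axis=0) > 0
        winner = np.argmax(ebr_stack, axis=0)  # ties: fission > fusion > intra
        names = np.array(["fission", "fusion", "intrachromosomal"], dtype=object)
        cls_arr[has_ebr] = names[winner[has_ebr]]
        cls_arr[(~has_ebr) & (hsb > 0)] = "msHSB"

        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": edges[:-1],
                    "cne_bases": cne_bases,
                    "cls": cls_arr,
                    "usable": usable,
                }
            )
        )
    if not rows:
        raise ValueError("no complete windows to scan")
    table = pd.concat(rows, ignore_index=True)

    usable = table[table["usable"]]
    mean_bases: Dict[str, float] = {}
    mean_density: Dict[str, float] = {}
    for cls in WINDOW_CLASSES:
        vals = usable.loc[usable["cls"] == cls, "cne_bases"]
        mean_bases[cls] = float(vals.mean()) if len(vals) else float("nan")
        mean_density[cls] = mean_bases[cls] / window if len(vals) else float("nan")
    gm = float(usable["cne_bases"].mean()) if len(usable) else float("nan")
    return WindowScanResult(
        table=table,
        class_mean_bases=mean_bases,
        class_mean_density=mean_density,
        genome_mean_bases=gm,
        genome_mean_density=gm / window,
        window_size=window,
    )


def distance_to_mshsb_density(
    scan: WindowScanResult, threshold: Optional[float] = None
) -> pd.Series:
    """Distance, in windows, from each zero-CNE usable window to the nearest
    same-chromosome window at or above the msHSB average density.

    Windows already at or above the average get 0; chromosomes with no
    qualifying window yield missing values.  Raises if the msHSB class is
    empty (the average would be undefined).
    """
    if threshold is None:
        avg = scan.class_mean_density.get("msHSB")
        if avg is None or np.isnan(avg):
            raise ValueError("no msHSB windows: average density undefined")
        threshold = avg
    thr_bases = threshold * scan.window_size
    table = scan.table
    out = pd.Series(np.nan, index=table.index)
    for _chrom, idx in table.groupby("chrom").groups.items():
        sub = table.loc[idx]
        usable = sub["usable"].to_numpy()
        bases = sub["cne_bases"].to_numpy()
        qual = np.flatnonzero(usable & (bases >= thr_bases))
        positions = np.arange(len(sub))
        dist = np.full(len(sub), np.nan)
        if len(qual):
            j = np.searchsorted(qual, positions)
            right = np.where(j < len(qual), qual[np.minimum(j, len(qual) - 1)], np.iinfo(np.int64).max // 2)
            left = np.where(j > 0, qual[np.maximum(j - 1, 0)], -(np.iinfo(np.int64).max // 2))
            dist = np.minimum(np.abs(positions - left), np.abs(right - positions)).astype(float)
        zero_mask = usable & (bases == 0)
        at_or_above = usable & (bases >= thr_bases)
        col = np.full(len(sub), np.nan)
        if len(qual):
            col[zero_mask] = dist[zero_mask]
        col[at_or_above] = 0.0
        out.loc[idx] = col
    return out


# ---------------------------------------------------------------------------
# rank tests


def _rankdata(values: np.ndarray) -> np.ndarray:
    """Mid-ranks (average ranks for ties)."""
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values), dtype=float)
    sv = values[order]
    i = 0
    while i < len(sv):
        j = i
        while j + 1 < len(sv) and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for x: #(x > y) pairs + half-credit for ties."""
    u = 0.0
    for xv in x:
        u += np.sum(xv > y) + 0.5 * np.sum(xv == y)
    return float(u)


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> Tuple[float, float]:
    """Mann-Whitney U test of x vs y.

    Exact p by enumeration of all group assignments of the pooled sample
    (ties included) when the pooled size is at most 12; otherwise a normal
    approximation with tie correction and a 0.5 continuity correction.
    Returns (U for x, p).
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError("alternative must be two-sided / greater / less")
    n, m = len(x), len(y)
    u_obs = _u_statistic(x, y)
    if n + m <= EXACT_LIMIT:
        pooled = np.concatenate([x, y])
        idx = range(n + m)
        us = []
        for comb in combinations(idx, n):
            mask = np.zeros(n + m, dtype=bool)
            mask[list(comb)] = True
            us.append(_u_statistic(pooled[mask], pooled[~mask]))
        us = np.asarray(us)
        eps = 1e-9
        p_ge = np.mean(us >= u_obs - eps)
        p_le = np.mean(us <= u_obs + eps)
        if alternative == "greater":
            p = p_ge
        elif alternative == "less":
            p = p_le
        else:
            p = min(1.0, 2.0 * min(p_ge, p_le))
        return u_obs, float(p)
    # normal approximation with tie correction
    N = n + m
    pooled = np.concatenate([x, y])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (N * (N - 1))
    mu = n * m / 2.0
    var = n * m / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        return u_obs, 1.0
    sd = np.sqrt(var)
    if alternative == "greater":
        z = (u_obs - mu - 0.5) / sd
        p = sps.norm.sf(z)
    elif alternative == "less":
        z = (u_obs - mu + 0.5) / sd
        p = sps.norm.cdf(z)
    else:
        z = (abs(u_obs - mu) - 0.5) / sd
        p = 2.0 * sps.norm.sf(max(z, 0.0))
    return u_obs, float(min(p, 1.0))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> Tuple[float, float]:
    """Kruskal-Wallis H with tie correction; p from chi-squared (k-1 df).

    With every observation identical the statistic is defined as 0 (p = 1).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(list(g), dtype=float) for g in groups]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("groups must be non-empty")
    pooled = np.concatenate(arrays)
    N = len(pooled)
    ranks = _rankdata(pooled)
    h = 0.0
    pos = 0
    for a in arrays:
        r = ranks[pos : pos + len(a)]
        h += r.sum() ** 2 / len(a)
        pos += len(a)
    h = 12.0 / (N * (N + 1)) * h - 3.0 * (N + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(counts**3 - counts) / (N**3 - N)
    if correction <= 0:
        return 0.0, 1.0
    h /= correction
    df = len(arrays) - 1
    p = float(sps.chi2.sf(h, df))
    return float(h), p
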
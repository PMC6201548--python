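"""Homology maps, interchromosomal event counting, and EBR detection.

A homology map describes, for each chromosome of a target species, the
ordered, signed list of reference (or ancestral) chromosome segments it is
built from — the abstraction behind comparative chromosome ideograms.  From
it we count fusions (junction-based: a chromosome concatenating k reference
units contributes k-1), fissions (piece-based: a unit present on m
chromosomes contributes m-1), classify evolutionary breakpoint regions
(EBRs) as fusion / fission / intrachromosomal, and estimate inversion counts
via signed sorting-by-reversals distance.

The junction/piece counting convention is the unique one consistent with the
chromosome-number identity ``#target = #units + fissions - fusions`` on a
complete map.
"""

from __future__ import annotations

import heapq
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

__all__ = [
    "UnitSet",
    "HomologySegment",
    "HomologyMap",
    "EBR",
    "EventCounts",
    "chicken_units",
    "ancestral_units",
    "build_homology_map",
    "count_interchromosomal_events",
    "detect_ebrs",
    "estimate_inversions",
    "estimate_map_inversions",
    "InversionCount",
]


@dataclass(frozen=True)
class UnitSet:
    """The reference units homology is expressed in.

    ``homolog_of`` groups units into reference homologs (e.g. the ancestral
    microchromosome unit that forms the p-arm of a fused reference
    chromosome belongs to that chromosome's homolog).  ``micro_units`` marks
    microchromosome units.
    """

    name: str
    units: Tuple[str, ...]
    homolog_of: Mapping[str, str] = field(default_factory=dict)
    micro_units: frozenset = frozenset()

    def homolog(self, unit: str) -> str:
        return self.homolog_of.get(unit, unit)

    def __contains__(self, unit: str) -> bool:
        return unit in self.units


_GGA_UNITS = tuple(
    [str(i) for i in range(1, 29) if i not in (16, 25)] + ["Z"]
)
_GGA_MICRO = frozenset(str(i) for i in range(10, 29) if i not in (16, 25))


def chicken_units() -> UnitSet:
    """Chicken chromosome units: GGA1-28 (no data for 16 and 25) plus Z;
    chromosome 4 (q+p) is a single unit."""
    return UnitSet(name="chicken", units=_GGA_UNITS, micro_units=_GGA_MICRO)


def ancestral_units() -> UnitSet:
    """Ancestral avian units: as chicken, but the microchromosome forming
    chicken 4p is its own unit '4p' (grouped under homolog '4')."""
    return UnitSet(
        name="ancestral-units",
        units=_GGA_UNITS + ("4p",),
        homolog_of={"4p": "4"},
        micro_units=_GGA_MICRO | {"4p"},
    )


@dataclass(frozen=True)
class HomologySegment:
    """One signed reference segment on a target chromosome.

    Reference/target coordinates may be None for order-only maps (curated
    karyotype fixtures)."""

    tgt_chrom: str
    unit: str
    strand: str = "+"
    tgt_start: Optional[int] = None
    tgt_end: Optional[int] = None
    ref_start: Optional[int] = None
    ref_end: Optional[int] = None
    note: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def has_coords(self) -> bool:
        return self.ref_start is not None and self.ref_end is not None


@dataclass
class HomologyMap:
    """Ordered signed segments per target chromosome."""

    segments: Dict[str, List[HomologySegment]]
    unit_set: Optional[UnitSet] = None
    species: str = ""

    def __post_init__(self) -> None:
        if self.unit_set is not None:
            for segs in self.segments.values():
                for s in segs:
                    if s.unit not in self.unit_set:
                        raise KeyError(
                            f"unknown unit {s.unit!r} for unit set {self.unit_set.name!r}"
                        )

    @property
    def chromosomes(self) -> List[str]:
        return list(self.segments)

    def units_present(self) -> Set[str]:
        return {s.unit for segs in self.segments.values() for s in segs}


@dataclass(frozen=True)
class EBR:
    """An evolutionary breakpoint region in reference coordinates."""

    unit: str
    start: int
    end: int
    cls: str  # 'fusion' | 'fission' | 'intrachromosomal'
    species: str = ""
    flanks: Tuple[str, ...] = ()
    excluded_from_cne: bool = False

    def __post_init__(self) -> None:
        if self.cls not in ("fusion", "fission", "intrachromosomal"):
            raise ValueError(f"invalid EBR class {self.cls!r}")
        if self.end <= self.start:
            raise ValueError("EBR interval must have positive length")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class EventCounts:
    fusions: int
    fissions: int
    intact_units: Set[str]  # intact reference homologs
    fused_micro_units: Set[str]
    intact_micro_units: Set[str]
    n_target_chromosomes: int
    n_units: int
    inversions_estimate: Optional[int] = None

    def identity_holds(self) -> bool:
        """#target chromosomes == #units + fissions - fusions."""
        return self.n_target_chromosomes == self.n_units + self.fissions - self.fusions


# ---------------------------------------------------------------------------
# building maps from anchored assemblies


def build_homology_map(
    chrom_chains: Mapping[str, Sequence[Tuple[str, int, int, str]]],
    sfs: Sequence,
    unit_set: Optional[UnitSet] = None,
    min_segment: int = 150_000,
    merge_gap: int = 1_000_000,
    species: str = "",
) -> HomologyMap:
    """Build a homology map from chromosome-level scaffold chains plus the
    SF coordinate map.

    ``chrom_chains`` maps each target chromosome to its ordered
    (scaffold, start, end, strand) fragments (e.g.
    :meth:`ChromosomeAssembly.member_chain`).  Adjacent colinear same-unit
    segments with reference gaps below ``merge_gap`` are merged; segments
    shorter than ``min_segment`` on the reference are absorbed or dropped.
    """
    by_scaffold: Dict[str, List] = defaultdict(list)
    for sf in sfs:
        by_scaffold[sf.scaffold].append(sf)
    for lst in by_scaffold.values():
        lst.sort(key=lambda s: s.tgt_start)

    segments: Dict[str, List[HomologySegment]] = {}
    for chrom, chain in chrom_chains.items():
        raw: List[HomologySegment] = []
        tpos = 0
        for scaffold, start, end, strand in chain:
            frag_sfs = [
                sf for sf in by_scaffold.get(scaffold, [])
                if sf.tgt_start >= start and sf.tgt_end <= end
            ]
            if strand == "-":
                frag_sfs = list(reversed(frag_sfs))
            for sf in frag_sfs:
                s_strand = sf.strand
                if strand == "-":
                    s_strand = "-" if s_strand == "+" else "+"
                seg_len = sf.tgt_length
                raw.append(
                    HomologySegment(
                        tgt_chrom=chrom,
                        unit=sf.ref_chrom,
                        strand=s_strand,
                        tgt_start=tpos,
                        tgt_end=tpos + seg_len,
                        ref_start=sf.ref_start,
                        ref_end=sf.ref_end,
                    )
                )
                tpos += seg_len
            tpos += max(end - start - sum(sf.tgt_length for sf in frag_sfs), 0)
        merged = _merge_segments(raw, merge_gap)
        merged = [
            s for s in merged
            if (s.ref_end - s.ref_start) >= min_segment
        ]
        merged = _merge_segments(merged, merge_gap)
        if merged:
            segments[chrom] = merged
    return HomologyMap(segments=segments, unit_set=unit_set, species=species)


def _merge_segments(
    segs: List[HomologySegment], merge_gap: int
) -> List[HomologySegment]:
    out: List[HomologySegment] = []
    for s in segs:
        if out:
            p = out[-1]
            if (
                p.unit == s.unit
                and p.strand == s.strand
                and p.has_coords
                and s.has_coords
            ):
                if p.strand == "+":
                    gap = s.ref_start - p.ref_end
                    ordered = s.ref_start >= p.ref_start
                else:
                    gap = p.ref_start - s.ref_end
                    ordered = p.ref_start >= s.ref_start
                if ordered and -merge_gap < gap < merge_gap:
                    out[-1] = HomologySegment(
                        tgt_chrom=p.tgt_chrom,
                        unit=p.unit,
                        strand=p.strand,
                        tgt_start=p.tgt_start,
                        tgt_end=s.tgt_end,
                        ref_start=min(p.ref_start, s.ref_start),
                        ref_end=max(p.ref_end, s.ref_end),
                    )
                    continue
        out.append(s)
    return out


# ---------------------------------------------------------------------------
# event counting


def count_interchromosomal_events(
    hmap: HomologyMap, unit_set: Optional[UnitSet] = None
) -> EventCounts:
    """Count fusions, fissions, and intact reference homologs.

    Fusions are junction-based (adjacent segments of distinct units); a
    same-unit adjacency, however scrambled, is intrachromosomal and does not
    count.  Fissions are piece-based over distinct target chromosomes.  A
    reference homolog is intact when each of its units occupies exactly one
    chromosome and no chromosome carrying it carries any other homolog.
    """
    if not hmap.segments:
        raise ValueError("empty homology map")
    unit_set = unit_set or hmap.unit_set
    fusions = 0
    unit_chroms: Dict[str, Set[str]] = defaultdict(set)
    chrom_units: Dict[str, Set[str]] = defaultdict(set)
    fused_units: Set[str] = set()
    for chrom, segs in hmap.segments.items():
        for s in segs:
            unit_chroms[s.unit].add(chrom)
            chrom_units[chrom].add(s.unit)
        for a, b in zip(segs, segs[1:]):
            if a.unit != b.unit:
                fusions += 1
                fused_units.add(a.unit)
                fused_units.add(b.unit)
    fissions = sum(len(cs) - 1 for cs in unit_chroms.values())

    homolog = unit_set.homolog if unit_set else (lambda u: u)
    chrom_homologs = {
        c: {homolog(u) for u in us} for c, us in chrom_units.items()
    }
    units_by_homolog: Dict[str, Set[str]] = defaultdict(set)
    for u in unit_chroms:
        units_by_homolog[homolog(u)].add(u)
    intact: Set[str] = set()
    for h, us in units_by_homolog.items():
        ok = True
        for u in us:
            if len(unit_chroms[u]) != 1:
                ok = False
                break
            c = next(iter(unit_chroms[u]))
            if chrom_homologs[c] != {h}:
                ok = False
                break
        if ok:
            intact.add(h)

    micro = unit_set.micro_units if unit_set else frozenset()
    fused_micro = {u for u in fused_units if u in micro}
    intact_micro = {
        u
        for u in unit_chroms
        if u in micro
        and len(unit_chroms[u]) == 1
        and chrom_units[next(iter(unit_chroms[u]))] == {u}
    }
    n_units = len(unit_chroms)
    return EventCounts(
        fusions=fusions,
        fissions=fissions,
        intact_units=intact,
        fused_micro_units=fused_micro,
        intact_micro_units=intact_micro,
        n_target_chromosomes=len(hmap.segments),
        n_units=n_units,
    )


# ---------------------------------------------------------------------------
# EBR detection


def detect_ebrs(
    hmap: HomologyMap,
    max_len: int = 100_000,
    ref_lengths: Optional[Mapping[str, int]] = None,
) -> List[EBR]:
    """Detect and classify EBRs in reference coordinates.

    Fission EBRs span the reference gap between consecutive same-unit
    segments landing on different target chromosomes; intrachromosomal EBRs
    span the gap between same-unit, same-chromosome segments broken in order
    or strand; fusion EBRs sit at each reference breakpoint flanking a
    distinct-unit junction.  Intervals are clipped to >= 1 bp; EBRs longer
    than ``max_len`` are kept but flagged as excluded from CNE analysis.
    Class precedence at a shared breakpoint: fission > fusion >
    intrachromosomal.
    """
    for segs in hmap.segments.values():
        for s in segs:
            if not s.has_coords:
                raise ValueError("EBR detection requires reference coordinates")

    by_unit: Dict[str, List[Tuple[HomologySegment, str, int]]] = defaultdict(list)
    for chrom, segs in hmap.segments.items():
        for idx, s in enumerate(segs):
            by_unit[s.unit].append((s, chrom, idx))
    for lst in by_unit.values():
        lst.sort(key=lambda t: t[0].ref_start)

    ebrs: Dict[Tuple[str, int, int], EBR] = {}

    def _emit(unit, start, end, cls, flanks, species):
        start, end = int(start), int(end)
        if end <= start:
            end = start + 1
        # stay inside the reference chromosome when its length is known
        if ref_lengths and unit in ref_lengths:
            L = int(ref_lengths[unit])
            end = min(end, L)
            start = max(min(start, end - 1), 0)
            if end <= start:
                start, end = max(L - 1, 0), L
        key = (unit, start, end)
        prec = {"fission": 2, "fusion": 1, "intrachromosomal": 0}
        old = ebrs.get(key)
        if old is not None and prec[old.cls] >= prec[cls]:
            return
        ebrs[key] = EBR(
            unit=unit,
            start=start,
            end=end,
            cls=cls,
            species=species,
            flanks=flanks,
            excluded_from_cne=(end - start) > max_len,
        )

    # same-unit reference adjacencies: fission / intrachromosomal
    for unit, lst in by_unit.items():
        for (a, ca, ia), (b, cb, ib) in zip(lst, lst[1:]):
            gap = (a.ref_end, b.ref_start)
            if ca != cb:
                _emit(unit, gap[0], gap[1], "fission",
                      (f"{ca}:{ia}", f"{cb}:{ib}"), hmap.species)
            else:
                adjacent = abs(ia - ib) == 1
                colinear = (
                    adjacent
                    and a.strand == b.strand
                    and (
                        (a.strand == "+" and ib == ia + 1)
                        or (a.strand == "-" and ib == ia - 1)
                    )
                )
                if not colinear:
                    _emit(unit, gap[0], gap[1], "intrachromosomal",
                          (f"{ca}:{ia}", f"{cb}:{ib}"), hmap.species)

    # distinct-unit junctions: fusion EBR at each flanking reference break
    for chrom, segs in hmap.segments.items():
        for idx in range(len(segs) - 1):
            a, b = segs[idx], segs[idx + 1]
            if a.unit == b.unit:
                continue
            for seg, side in ((a, "right"), (b, "left")):
                broken_high = (side == "right") == (seg.strand == "+")
                lst = by_unit[seg.unit]
                if broken_high:
                    nxt = [
                        t[0].ref_start for t in lst if t[0].ref_start >= seg.ref_end
                    ]
                    hi = min(nxt) if nxt else (
                        ref_lengths[seg.unit] if ref_lengths and seg.unit in ref_lengths
                        else seg.ref_end + 1
                    )
                    _emit(seg.unit, seg.ref_end, hi, "fusion",
                          (f"{chrom}:{idx}", f"{chrom}:{idx + 1}"), hmap.species)
                else:
                    prv = [t[0].ref_end for t in lst if t[0].ref_end <= seg.ref_start]
                    lo = max(prv) if prv else 0
                    _emit(seg.unit, lo, seg.ref_start, "fusion",
                          (f"{chrom}:{idx}", f"{chrom}:{idx + 1}"), hmap.species)
    return sorted(ebrs.values(), key=lambda e: (e.unit, e.start))


# ---------------------------------------------------------------------------
# inversion estimation


class InversionCount(int):
    """An integer inversion count knowing whether it is exact or a
    breakpoint-based lower bound."""

    exact: bool

    def __new__(cls, value: int, exact: bool):
        obj = super().__new__(cls, value)
        obj.exact = exact
        return obj


def _breakpoints(perm: Tuple[int, ...]) -> int:
    ext = (0,) + perm + (len(perm) + 1,)
    return sum(1 for x, y in zip(ext, ext[1:]) if y - x != 1)


def _reversal_neighbors(perm: Tuple[int, ...]):
    n = len(perm)
    for i in range(n):
        for j in range(i, n):
            yield (
                perm[:i]
                + tuple(-x for x in reversed(perm[i : j + 1]))
                + perm[j + 1 :]
            )


_BFS_TABLE_LIMIT = 6
_bfs_tables: Dict[int, Dict[Tuple[int, ...], int]] = {}


def _bfs_distance_table(n: int) -> Dict[Tuple[int, ...], int]:
    """All reversal distances for signed permutations of size n, by a single
    breadth-first sweep from the identity (reversal moves are involutions,
    so d(identity, p) = d(p, identity))."""
    table = _bfs_tables.get(n)
    if table is None:
        from collections import deque

        ident = tuple(range(1, n + 1))
        table = {ident: 0}
        queue = deque([ident])
        while queue:
            cur = queue.popleft()
            d = table[cur] + 1
            for nxt in _reversal_neighbors(cur):
                if nxt not in table:
                    table[nxt] = d
                    queue.append(nxt)
        _bfs_tables[n] = table
    return table


def estimate_inversions(
    perm: Sequence[int], exact_limit: int = 10, method: str = "auto"
) -> InversionCount:
    """Signed sorting-by-reversals distance of a signed permutation.

    Exact for up to ``exact_limit`` elements: by default a cached
    breadth-first distance table serves n <= 6 and an A* search (with the
    admissible ceil(breakpoints/2) bound) the rest; ``method`` can force
    ``"astar"`` or ``"table"``.  Beyond the limit the breakpoint-based lower
    bound is returned, labeled inexact.
    """
    if method not in ("auto", "astar", "table"):
        raise ValueError("method must be auto / astar / table")
    perm = tuple(int(x) for x in perm)
    n = len(perm)
    if n == 0:
        raise ValueError("empty permutation")
    if sorted(abs(x) for x in perm) != list(range(1, n + 1)) or 0 in perm:
        raise ValueError("input is not a signed permutation of 1..n")
    identity = tuple(range(1, n + 1))
    if n > exact_limit:
        return InversionCount(-(-_breakpoints(perm) // 2), False)
    use_table = method == "table" or (method == "auto" and n <= _BFS_TABLE_LIMIT)
    if use_table:
        if n > _BFS_TABLE_LIMIT:
            raise ValueError(f"distance table only built for n <= {_BFS_TABLE_LIMIT}")
        return InversionCount(_bfs_distance_table(n)[perm], True)
    # A* over reversal moves
    h0 = -(-_breakpoints(perm) // 2)
    heap = [(h0, 0, perm)]
    best: Dict[Tuple[int, ...], int] = {perm: 0}
    while heap:
        f, g, cur = heapq.heappop(heap)
        if cur == identity:
            return InversionCount(g, True)
        if g > best.get(cur, 1 << 30):
            continue
        for nxt in _reversal_neighbors(cur):
            ng = g + 1
            if ng < best.get(nxt, 1 << 30):
                best[nxt] = ng
                heapq.heappush(
                    heap, (ng + -(-_breakpoints(nxt) // 2), ng, nxt)
                )
    raise AssertionError("unreachable: reversal sort always terminates")


def _signed_order(segs: List[HomologySegment]) -> Tuple[int, ...]:
    ranked = sorted(range(len(segs)), key=lambda i: segs[i].ref_start)
    rank_of = {i: r + 1 for r, i in enumerate(ranked)}
    return tuple(
        rank_of[i] if segs[i].strand == "+" else -rank_of[i]
        for i in range(len(segs))
    )


def estimate_map_inversions(hmap: HomologyMap) -> InversionCount:
    """Sum of per-(unit, chromosome) reversal distances.

    Each group's segments, in target order, form a signed permutation of
    their reference ranks; since a chromosome's global orientation is
    arbitrary, the minimum over the permutation and its mirror is used.
    Single-segment groups contribute 0.
    """
    total = 0
    exact = True
    groups: Dict[Tuple[str, str], List[HomologySegment]] = defaultdict(list)
    for chrom, segs in hmap.segments.items():
        for s in segs:
            groups[(s.unit, chrom)].append(s)
    for (_unit, _chrom), segs in groups.items():
        if len(segs) < 2:
            continue
        if not all(s.has_coords for s in segs):
            raise ValueError("inversion estimation requires reference coordinates")
        perm = _signed_order(segs)
        mirror = tuple(-x for x in reversed(perm))
        d1 = estimate_inversions(perm)
        d2 = estimate_inversions(mirror)
        d = min(int(d1), int(d2))
        exact = exact and d1.exact and d2.exact
        total += d
    return InversionCount(total, exact)
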
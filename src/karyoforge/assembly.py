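"""Reference-assisted assembly of scaffolds into predicted chromosome
fragments (PCFs).

The procedure mirrors the two-round reference-assisted strategy used for
fragmented genomes: alignment blocks are merged into syntenic fragments
(SFs); scaffold-internal joins whose flanking SFs disagree with the
reference geometry are flagged as putatively chimeric; an absolute
spanning-read-pair coverage threshold is calibrated against PCR outcomes to
maximize agreement; joins below the threshold (and not rescued by PCR) are
split; and the resulting scaffold fragments are chained along each
reference chromosome into ordered, oriented PCFs.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .genome import AssemblyStats, compute_n50, percent_of_assembly
from .simulate import AlignmentBlock, Scaffold

logger = logging.getLogger(__name__)

__all__ = [
    "SyntenicFragment",
    "AssemblyParams",
    "PCF",
    "PcfMember",
    "Join",
    "CalibrationResult",
    "build_syntenic_fragments",
    "find_conflicting_joins",
    "attach_coverage",
    "calibrate_threshold",
    "assemble_pcfs",
    "pcf_stats",
]


@dataclass(frozen=True)
class SyntenicFragment:
    """A resolution-merged colinear mapping of a scaffold interval to one
    reference chromosome."""

    scaffold: str
    tgt_start: int
    tgt_end: int
    ref_chrom: str
    ref_start: int
    ref_end: int
    strand: str
    resolution: int = 150_000

    @property
    def tgt_length(self) -> int:
        return self.tgt_end - self.tgt_start

    @property
    def ref_length(self) -> int:
        return self.ref_end - self.ref_start

    @property
    def ref_mid(self) -> float:
        return 0.5 * (self.ref_start + self.ref_end)


@dataclass
class AssemblyParams:
    """Knobs of the SF merge and split stages.

    ``resolution`` plays the classic synteny-resolution role: alignment gaps
    below it are bridged and fragments shorter than it are discarded.
    ``min_intracov_threshold`` is an absolute spanning-pair count below which
    a conflicting join is split (usually supplied by calibration).
    """

    window_size: int = 10
    resolution: int = 150_000
    min_intracov_threshold: int = 0

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.min_intracov_threshold < 0:
            raise ValueError("threshold must be >= 0")


@dataclass
class PcfMember:
    """A contiguous scaffold fragment placed in a PCF.

    ``strand`` is the orientation of the scaffold interval as laid out in the
    PCF ('+' keeps scaffold coordinates ascending).
    """

    scaffold: str
    start: int
    end: int
    strand: str
    sfs: List[SyntenicFragment] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PCF:
    id: str
    members: List[PcfMember]

    @property
    def length(self) -> int:
        return sum(m.length for m in self.members)


@dataclass
class Join:
    """An intra-scaffold junction between two consecutive SFs."""

    scaffold: str
    left_index: int
    right_index: int
    gap_start: int  # tgt_end of the left SF
    gap_end: int  # tgt_start of the right SF
    conflict: bool
    reason: str
    offset: Optional[int] = None  # canonical junction offset (from coverage)
    coverage: Optional[int] = None

    @property
    def span(self) -> int:
        return self.gap_end - self.gap_start


@dataclass
class CalibrationResult:
    threshold: int
    agreement: int
    tested: int

    def __post_init__(self) -> None:
        if self.agreement > self.tested:
            raise ValueError("agreement cannot exceed tested joins")


# ---------------------------------------------------------------------------


def _colinear(a: AlignmentBlock, b: AlignmentBlock, resolution: int) -> bool:
    if a.ref_chrom != b.ref_chrom or a.strand != b.strand:
        return False
    tgt_gap = b.tgt_start - a.tgt_end
    if not (0 <= tgt_gap < resolution):
        return False
    if a.strand == "+":
        ref_gap = b.ref_start - a.ref_end
    else:
        ref_gap = a.ref_start - b.ref_end
    return -resolution < ref_gap < resolution and ref_gap > -min(
        a.ref_end - a.ref_start, b.ref_end - b.ref_start
    )


def build_syntenic_fragments(
    blocks: Iterable[AlignmentBlock], params: AssemblyParams
) -> List[SyntenicFragment]:
    """Merge colinear alignment blocks into SFs and drop sub-resolution ones.

    Consecutive blocks of a scaffold on the same reference chromosome and
    strand, with gaps below the resolution on both genomes and consistent
    ordering, are merged.  SFs shorter than the resolution on the target are
    discarded.
    """
    by_scaffold: Dict[str, List[AlignmentBlock]] = defaultdict(list)
    for b in blocks:
        if b.ref_end <= b.ref_start or b.tgt_end <= b.tgt_start:
            raise ValueError(f"malformed block with non-positive span: {b}")
        by_scaffold[b.scaffold].append(b)

    sfs: List[SyntenicFragment] = []
    for scaffold in sorted(by_scaffold):
        blist = sorted(by_scaffold[scaffold], key=lambda b: b.tgt_start)
        run = [blist[0]]
        for b in blist[1:]:
            if _colinear(run[-1], b, params.resolution):
                run.append(b)
            else:
                sfs.append(_run_to_sf(run, params.resolution))
                run = [b]
        sfs.append(_run_to_sf(run, params.resolution))
    kept = [sf for sf in sfs if sf.tgt_length >= params.resolution]
    return kept


def _run_to_sf(run: List[AlignmentBlock], resolution: int) -> SyntenicFragment:
    first, last = run[0], run[-1]
    ref_start = min(b.ref_start for b in run)
    ref_end = max(b.ref_end for b in run)
    return SyntenicFragment(
        scaffold=first.scaffold,
        tgt_start=first.tgt_start,
        tgt_end=last.tgt_end,
        ref_chrom=first.ref_chrom,
        ref_start=ref_start,
        ref_end=ref_end,
        strand=first.strand,
        resolution=resolution,
    )


def find_conflicting_joins(
    sfs: Sequence[SyntenicFragment], params: AssemblyParams
) -> List[Join]:
    """Flag scaffold-internal joins whose flanking SFs disagree with the
    reference: different chromosomes, a reference gap above the resolution,
    or inconsistent strand geometry."""
    by_scaffold: Dict[str, List[SyntenicFragment]] = defaultdict(list)
    for sf in sfs:
        by_scaffold[sf.scaffold].append(sf)
    joins: List[Join] = []
    for scaffold in sorted(by_scaffold):
        slist = sorted(by_scaffold[scaffold], key=lambda s: s.tgt_start)
        for i in range(len(slist) - 1):
            a, b = slist[i], slist[i + 1]
            conflict, reason = _classify_join(a, b, params.resolution)
            joins.append(
                Join(
                    scaffold=scaffold,
                    left_index=i,
                    right_index=i + 1,
                    gap_start=a.tgt_end,
                    gap_end=b.tgt_start,
                    conflict=conflict,
                    reason=reason,
                )
            )
    return joins


def _classify_join(a, b, resolution) -> Tuple[bool, str]:
    if a.ref_chrom != b.ref_chrom:
        return True, "different reference chromosomes"
    if a.strand != b.strand:
        return True, "strand flip"
    if a.strand == "+":
        ref_gap = b.ref_start - a.ref_end
        ordered = b.ref_start >= a.ref_start
    else:
        ref_gap = a.ref_start - b.ref_end
        ordered = a.ref_start >= b.ref_start
    if not ordered:
        return True, "reference order inverted"
    if abs(ref_gap) > resolution:
        return True, f"reference gap {ref_gap} above resolution"
    return False, "colinear"


def attach_coverage(
    joins: Sequence[Join], coverage: Iterable[Tuple[str, int, int]]
) -> List[Join]:
    """Assign each join the spanning-pair count whose junction offset falls
    inside its unaligned gap.  Missing coverage is treated as 0 (logged)."""
    cov_by_scaffold: Dict[str, List[Tuple[int, int]]] = defaultdict(list)
    for sid, off, pairs in coverage:
        cov_by_scaffold[sid].append((int(off), int(pairs)))
    for join in joins:
        hit = None
        for off, pairs in cov_by_scaffold.get(join.scaffold, []):
            if join.gap_start <= off <= join.gap_end:
                hit = (off, pairs)
                break
        if hit is None:
            logger.warning(
                "no coverage for join %s:[%d,%d] - treating as 0",
                join.scaffold, join.gap_start, join.gap_end,
            )
            join.offset = join.gap_start
            join.coverage = 0
        else:
            join.offset, join.coverage = hit
    return list(joins)


def calibrate_threshold(
    joins: Sequence[Join],
    pcr: Mapping[Tuple[str, int], str],
) -> CalibrationResult:
    """Choose the spanning-pair threshold that maximizes agreement with PCR.

    ``pcr`` maps (scaffold, junction offset) to 'confirmed' / 'refuted' /
    'untestable'.  Agreement at threshold T counts confirmed joins with
    coverage >= T plus refuted joins with coverage < T; the smallest
    maximizing T is returned (most conservative splitting).  Untestable
    joins contribute nothing.
    """
    tested: List[Tuple[int, str]] = []
    for j in joins:
        status = pcr.get((j.scaffold, j.offset))
        if status in ("confirmed", "refuted"):
            if j.coverage is None:
                raise ValueError("join has no coverage; run attach_coverage first")
            tested.append((j.coverage, status))
    if not tested:
        raise ValueError("no PCR-tested joins to calibrate against")
    candidates = sorted({0} | {cov + 1 for cov, _ in tested})
    best_t, best_agreement = 0, -1
    for t in candidates:
        agreement = sum(
            1
            for cov, status in tested
            if (status == "confirmed" and cov >= t)
            or (status == "refuted" and cov < t)
        )
        if agreement > best_agreement:
            best_t, best_agreement = t, agreement
    return CalibrationResult(threshold=best_t, agreement=best_agreement, tested=len(tested))


# ---------------------------------------------------------------------------


def assemble_pcfs(
    scaffolds: Sequence[Scaffold],
    sfs: Sequence[SyntenicFragment],
    coverage: Iterable[Tuple[str, int, int]],
    params: AssemblyParams,
    confirmed: Optional[Set[Tuple[str, int]]] = None,
    threshold: Optional[int] = None,
) -> Tuple[List[PCF], List[dict]]:
    """Split weakly supported conflicting joins and chain the resulting
    scaffold fragments into PCFs along each reference chromosome.

    A conflicting join is split when its spanning coverage is below the
    threshold, unless its structure was PCR-confirmed (confirmed structures
    are inputs, never split).  Fragments are assigned to the reference
    chromosome carrying most of their aligned length, ordered by the
    length-weighted reference midpoint of their SFs, and oriented so the
    reference coordinate ascends.  Returns (PCFs, split registry).
    """
    confirmed = confirmed or set()
    if threshold is None:
        threshold = params.min_intracov_threshold

    by_scaffold: Dict[str, List[SyntenicFragment]] = defaultdict(list)
    for sf in sfs:
        by_scaffold[sf.scaffold].append(sf)

    members: List[PcfMember] = []
    split_registry: List[dict] = []
    for scaffold in sorted(by_scaffold):
        slist = sorted(by_scaffold[scaffold], key=lambda s: s.tgt_start)
        joins = attach_coverage(find_conflicting_joins(slist, params), coverage)
        cut_after: Set[int] = set()
        for j in joins:
            if not j.conflict:
                continue
            if (j.scaffold, j.offset) in confirmed:
                continue
            if (j.coverage or 0) < threshold:
                cut_after.add(j.left_index)
                split_registry.append(
                    {
                        "scaffold": scaffold,
                        "offset": j.offset,
                        "coverage": j.coverage,
                        "reason": j.reason,
                    }
                )
        run: List[SyntenicFragment] = []
        for i, sf in enumerate(slist):
            run.append(sf)
            if i in cut_after or i == len(slist) - 1:
                members.append(_make_member(run))
                run = []

    # chain members along each reference chromosome
    by_ref: Dict[str, List[PcfMember]] = defaultdict(list)
    for m in members:
        ref_lengths: Dict[str, int] = defaultdict(int)
        for sf in m.sfs:
            ref_lengths[sf.ref_chrom] += sf.tgt_length
        assigned = max(sorted(ref_lengths), key=lambda c: ref_lengths[c])
        by_ref[assigned].append(m)

    pcfs: List[PCF] = []
    for ref_chrom in sorted(by_ref):
        ms = by_ref[ref_chrom]
        ms.sort(key=lambda m: _weighted_mid(m, ref_chrom))
        pcfs.append(PCF(id=f"PCF_{ref_chrom}", members=ms))
    return pcfs, split_registry


def _make_member(run: List[SyntenicFragment]) -> PcfMember:
    start = run[0].tgt_start
    end = run[-1].tgt_end
    plus = sum(sf.tgt_length for sf in run if sf.strand == "+")
    minus = sum(sf.tgt_length for sf in run if sf.strand == "-")
    strand = "+" if plus >= minus else "-"
    return PcfMember(
        scaffold=run[0].scaffold, start=start, end=end, strand=strand, sfs=list(run)
    )


def _weighted_mid(m: PcfMember, ref_chrom: str) -> float:
    num = den = 0.0
    for sf in m.sfs:
        if sf.ref_chrom == ref_chrom:
            num += sf.ref_mid * sf.tgt_length
            den += sf.tgt_length
    return num / den if den else 0.0


def pcf_stats(pcfs: Sequence[PCF], scaffolds: Sequence[Scaffold]) -> AssemblyStats:
    """PCF counts, total length, N50 and percent of the input assembly."""
    if not pcfs:
        raise ValueError("no PCFs")
    lengths = [p.length for p in pcfs]
    total = sum(lengths)
    original = sum(s.length for s in scaffolds)
    pct = min(percent_of_assembly(min(total, original), original), 100.0)
    return AssemblyStats(
        n_units=len(pcfs),
        total_length=total,
        n50=compute_n50(lengths),
        pct_placed=pct,
        pct_oriented=pct,
    )
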
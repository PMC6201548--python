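"""Anchoring PCFs to chromosomes with BAC/FISH marker evidence.

Each BAC marker has known reference coordinates and, from hybridization, an
observed chromosome and order index.  Mapping markers through the syntenic
fragments onto PCF offsets lets us place each PCF on a chromosome, orient it
(two markers with distinct offsets suffice), order PCFs along the chromosome
by median observed index, and detect PCF-FISH disagreements (markers of one
PCF on several chromosomes, or non-monotone order).

Two disagreement policies exist: ``"report"`` leaves conflicting PCFs
unplaced and records them; ``"split"`` re-places PCF members individually
using their own markers, which recovers chromosome structure the reference
ordering cannot see (target-specific fissions, fusions and multi-scaffold
inversions).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from statistics import median
from typing import Dict, List, Mapping, Sequence, Tuple

from .assembly import PCF, PcfMember, SyntenicFragment
from .genome import AssemblyStats, compute_n50, percent_of_assembly
from .simulate import BacMarker, Scaffold

__all__ = [
    "BacObservation",
    "BacLocation",
    "ChromosomeAssembly",
    "PlacedUnit",
    "locate_bacs_on_pcfs",
    "anchor",
    "anchoring_stats",
    "export_agp",
    "parse_agp",
]

AGP_GAP_LENGTH = 100


@dataclass(frozen=True)
class BacObservation:
    bac_id: str
    chrom: str
    order_index: int


@dataclass(frozen=True)
class BacLocation:
    bac_id: str
    pcf_id: str
    member_index: int
    offset: int  # offset within the PCF as laid out
    spans_boundary: bool = False


@dataclass
class PlacedUnit:
    """A placed, possibly oriented chain of scaffold fragments."""

    id: str
    strand: str  # '+', '-' or '?' (unoriented)
    members: List[PcfMember]
    order_key: float = 0.0

    @property
    def length(self) -> int:
        return sum(m.length for m in self.members)


@dataclass
class ChromosomeAssembly:
    chrom: str
    units: List[PlacedUnit] = field(default_factory=list)

    @property
    def placed_length(self) -> int:
        return sum(u.length for u in self.units)

    @property
    def oriented_length(self) -> int:
        return sum(u.length for u in self.units if u.strand != "?")

    def member_chain(self) -> List[Tuple[str, int, int, str]]:
        """Flattened (scaffold, start, end, strand) in chromosomal order."""
        chain = []
        for u in self.units:
            ms = u.members
            if u.strand == "-":
                ms = list(reversed(ms))
            for m in ms:
                strand = m.strand
                if u.strand == "-":
                    strand = "-" if strand == "+" else "+"
                chain.append((m.scaffold, m.start, m.end, strand))
        return chain


# ---------------------------------------------------------------------------


def _member_layout(pcf: PCF) -> List[Tuple[int, PcfMember]]:
    """(pcf offset of member start, member) for each member as laid out."""
    out = []
    off = 0
    for m in pcf.members:
        out.append((off, m))
        off += m.length
    return out


def locate_bacs_on_pcfs(
    bacs: Sequence[BacMarker],
    sfs: Sequence[SyntenicFragment],
    pcfs: Sequence[PCF],
) -> Tuple[Dict[str, BacLocation], List[str]]:
    """Map BAC reference coordinates through the SF map to PCF offsets.

    Returns (locations by bac id, unmapped bac ids).  A BAC whose reference
    interval maps into two PCF members is flagged as spanning a boundary.
    """
    # index SFs by reference chromosome for interval lookup
    by_ref: Dict[str, List[SyntenicFragment]] = defaultdict(list)
    for sf in sfs:
        by_ref[sf.ref_chrom].append(sf)
    for lst in by_ref.values():
        lst.sort(key=lambda s: s.ref_start)

    # index members by scaffold interval
    member_index: Dict[str, List[Tuple[int, int, str, int, int, PcfMember]]] = defaultdict(list)
    # scaffold -> (start, end, pcf_id, member_idx, member_pcf_offset, member)
    for pcf in pcfs:
        for mi, (moff, m) in enumerate(_member_layout(pcf)):
            member_index[m.scaffold].append((m.start, m.end, pcf.id, mi, moff, m))

    locations: Dict[str, BacLocation] = {}
    unmapped: List[str] = []
    for bac in bacs:
        hits = []
        mid = (bac.ref.start + bac.ref.end) // 2
        for sf in by_ref.get(bac.ref.chrom, []):
            if sf.ref_start <= mid < sf.ref_end:
                if sf.strand == "+":
                    spos = sf.tgt_start + (mid - sf.ref_start)
                else:
                    spos = sf.tgt_end - 1 - (mid - sf.ref_start)
                hits.append((sf, spos))
        if not hits:
            unmapped.append(bac.id)
            continue
        located = []
        for sf, spos in hits:
            for start, end, pcf_id, mi, moff, member in member_index.get(sf.scaffold, []):
                if start <= spos < end:
                    located.append((pcf_id, mi, moff, spos - start, end - start, member))
        if not located:
            unmapped.append(bac.id)
            continue
        pcf_ids = {(p, m) for p, m, *_ in located}
        pcf_id, mi, moff, within, member_len, member = located[0]
        # member strand decides direction within the layout
        if member.strand == "-":
            within = member_len - 1 - within
        locations[bac.id] = BacLocation(
            bac_id=bac.id,
            pcf_id=pcf_id,
            member_index=mi,
            offset=moff + within,
            spans_boundary=len(pcf_ids) > 1,
        )
    return locations, unmapped


def _concordance(pairs: List[Tuple[float, float]]) -> int:
    """Kendall-style sign: +1 if all pairs concordant, -1 if all discordant,
    0 otherwise (mixed or fewer than 2 distinct points)."""
    pos = neg = 0
    for i in range(len(pairs)):
        for j in range(i + 1, len(pairs)):
            dx = pairs[j][0] - pairs[i][0]
            dy = pairs[j][1] - pairs[i][1]
            if dx * dy > 0:
                pos += 1
            elif dx * dy < 0:
                neg += 1
    if pos and not neg:
        return 1
    if neg and not pos:
        return -1
    return 0


def anchor(
    pcfs: Sequence[PCF],
    locations: Mapping[str, BacLocation],
    observations: Sequence[BacObservation],
    policy: str = "report",
    unmapped: Sequence[str] = (),
) -> Tuple[Dict[str, ChromosomeAssembly], List[dict]]:
    """Place and orient PCFs on chromosomes from FISH observations.

    Returns (assemblies by chromosome, disagreement records).  With the
    default ``"report"`` policy a PCF whose markers disagree (multiple
    chromosomes, or non-monotone order) is left unplaced; with ``"split"``
    its members are re-placed individually on the evidence of their own
    markers.
    """
    if policy not in ("report", "split"):
        raise ValueError("policy must be 'report' or 'split'")
    obs_by_bac: Dict[str, BacObservation] = {}
    for ob in observations:
        if isinstance(ob, tuple):
            ob = BacObservation(*ob)
        obs_by_bac[ob.bac_id] = ob

    known = set(locations) | set(unmapped)
    hits_by_pcf: Dict[str, List[Tuple[int, int, str, int]]] = defaultdict(list)
    # pcf -> (offset, member_index, chrom, order_index)
    for bid in obs_by_bac:
        if bid not in known:
            raise KeyError(f"observation references unknown BAC {bid!r}")
    for bid, loc in locations.items():
        ob = obs_by_bac.get(bid)
        if ob is None:
            continue
        hits_by_pcf[loc.pcf_id].append(
            (loc.offset, loc.member_index, ob.chrom, ob.order_index)
        )

    assemblies: Dict[str, ChromosomeAssembly] = {}
    disagreements: List[dict] = []

    def _add(chrom: str, unit: PlacedUnit) -> None:
        assemblies.setdefault(chrom, ChromosomeAssembly(chrom)).units.append(unit)

    for pcf in pcfs:
        hits = sorted(hits_by_pcf.get(pcf.id, []))
        if not hits:
            continue
        chroms = {h[2] for h in hits}
        pairs = [(h[0], h[3]) for h in hits]
        conc = _concordance(pairs)
        distinct_offsets = len({h[0] for h in hits})
        monotone = conc != 0 or distinct_offsets < 2
        if len(chroms) == 1 and monotone:
            chrom = next(iter(chroms))
            strand = {1: "+", -1: "-", 0: "?"}[conc if distinct_offsets >= 2 else 0]
            _add(
                chrom,
                PlacedUnit(
                    id=pcf.id,
                    strand=strand,
                    members=list(pcf.members),
                    order_key=median(h[3] for h in hits),
                ),
            )
            continue
        # disagreement
        disagreements.append(
            {
                "pcf": pcf.id,
                "chromosomes": sorted(chroms),
                "reason": "multiple chromosomes" if len(chroms) > 1 else "non-monotone order",
            }
        )
        if policy == "report":
            continue
        # split policy: place each member on the evidence of its own markers
        layout = _member_layout(pcf)
        by_member: Dict[int, List[Tuple[int, str, int]]] = defaultdict(list)
        for off, mi, chrom, order in hits:
            by_member[mi].append((off, chrom, order))
        _place_members(pcf, layout, by_member, _add)

    for asm in assemblies.values():
        asm.units.sort(key=lambda u: u.order_key)
    return assemblies, disagreements


def _place_members(pcf, layout, by_member, add) -> None:
    """Place every observed member of a disagreeing PCF as its own unit.

    Chromosome by majority vote of the member's markers, position by the
    median observed index, orientation by offset/order concordance; members
    without any observed marker travel with their nearest observed neighbor
    in PCF order (preceding if any, else following).
    """
    observed = [mi for mi in range(len(layout)) if by_member.get(mi)]
    if not observed:
        return
    attach: Dict[int, List[int]] = defaultdict(list)  # observed mi -> trailing followers
    prepend: Dict[int, List[int]] = defaultdict(list)
    for mi in range(len(layout)):
        if by_member.get(mi):
            continue
        before = [o for o in observed if o < mi]
        if before:
            attach[max(before)].append(mi)
        else:
            prepend[min(o for o in observed if o > mi)].append(mi)

    for k, mi in enumerate(observed):
        hits = by_member[mi]
        votes: Dict[str, int] = defaultdict(int)
        for _o, c, _r in hits:
            votes[c] += 1
        chrom = max(sorted(votes), key=lambda c: votes[c])
        moff, m = layout[mi]
        pairs = [(off - moff, r) for off, _c, r in hits]
        conc = _concordance(pairs)
        strand = m.strand
        if conc == -1:
            strand = "-" if strand == "+" else "+"
        elif conc == 0 and len({p[0] for p in pairs}) >= 2:
            strand = m.strand  # internally scrambled; keep as laid
        elif len({p[0] for p in pairs}) < 2:
            strand = "?"
        members: List[PcfMember] = []
        for pm in prepend.get(mi, ()):
            _poff, pmem = layout[pm]
            members.append(PcfMember(pmem.scaffold, pmem.start, pmem.end, pmem.strand, pmem.sfs))
        members.append(PcfMember(m.scaffold, m.start, m.end, strand, m.sfs))
        for fm in attach.get(mi, ()):
            _foff, fmem = layout[fm]
            members.append(PcfMember(fmem.scaffold, fmem.start, fmem.end, fmem.strand, fmem.sfs))
        add(
            chrom,
            PlacedUnit(
                id=f"{pcf.id}.{k + 1}",
                strand="+",
                members=members,
                order_key=float(median(h[2] for h in hits)),
            ),
        )


def anchoring_stats(
    assemblies: Mapping[str, ChromosomeAssembly],
    scaffolds: Sequence[Scaffold],
) -> AssemblyStats:
    """Placed/oriented lengths and percentages over the original assembly."""
    original = sum(s.length for s in scaffolds)
    placed = sum(a.placed_length for a in assemblies.values())
    # an unoriented unit contributes nothing to the oriented total, and
    # members left '?' inside an oriented unit stay unoriented too
    oriented = 0
    n_units = 0
    lengths = []
    for a in assemblies.values():
        for u in a.units:
            n_units += 1
            lengths.append(u.length)
            if u.strand == "?":
                continue
            for m in u.members:
                if m.strand != "?":
                    oriented += m.length
    pct_placed = percent_of_assembly(min(placed, original), original) if original else 0.0
    pct_oriented = percent_of_assembly(min(oriented, original), original) if original else 0.0
    return AssemblyStats(
        n_units=n_units,
        total_length=placed,
        n50=compute_n50(lengths) if lengths else 0,
        pct_placed=pct_placed,
        pct_oriented=min(pct_oriented, pct_placed),
    )


# ---------------------------------------------------------------------------
# AGP v2.1


def export_agp(assemblies: Mapping[str, ChromosomeAssembly]) -> List[str]:
    """Serialize assemblies as AGP v2.1 lines.

    One W row per scaffold fragment, with 100-bp unknown-sized gap rows
    (type "contig", evidence "map") between components.  Coordinates are
    1-based inclusive; unoriented components get orientation '?'.
    """
    lines = ["##agp-version\t2.1"]
    for chrom in sorted(assemblies):
        asm = assemblies[chrom]
        obj_pos = 0
        part = 0
        chain = asm.member_chain()
        for k, (scaffold, start, end, strand) in enumerate(chain):
            if end <= start:
                raise ValueError("component with non-positive length")
            if k > 0:
                part += 1
                lines.append(
                    f"{chrom}\t{obj_pos + 1}\t{obj_pos + AGP_GAP_LENGTH}\t{part}\t"
                    f"U\t{AGP_GAP_LENGTH}\tcontig\tyes\tmap"
                )
                obj_pos += AGP_GAP_LENGTH
            part += 1
            length = end - start
            lines.append(
                f"{chrom}\t{obj_pos + 1}\t{obj_pos + length}\t{part}\t"
                f"W\t{scaffold}\t{start + 1}\t{end}\t{strand}"
            )
            obj_pos += length
    return lines


def parse_agp(lines: Sequence[str]) -> Dict[str, List[Tuple[str, int, int, str]]]:
    """Inverse of :func:`export_agp`: chromosome -> ordered component chain
    of (scaffold, start, end, strand), 0-based half-open."""
    chains: Dict[str, List[Tuple[str, int, int, str]]] = defaultdict(list)
    last_end: Dict[str, int] = {}
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        chrom, obj_beg, obj_end, _part, ctype = parts[:5]
        obj_beg, obj_end = int(obj_beg), int(obj_end)
        if chrom in last_end and obj_beg != last_end[chrom] + 1:
            raise ValueError(f"non-contiguous object coordinates for {chrom}")
        last_end[chrom] = obj_end
        if ctype in ("N", "U"):
            continue
        scaffold, comp_beg, comp_end, orientation = parts[5], int(parts[6]), int(parts[7]), parts[8]
        if comp_end < comp_beg:
            raise ValueError("invalid component coordinates")
        chains[chrom].append((scaffold, comp_beg - 1, comp_end, orientation))
    # overlapping components within a scaffold are an error
    for chrom, chain in chains.items():
        seen: Dict[str, List[Tuple[int, int]]] = defaultdict(list)
        for scaffold, s, e, _o in chain:
            for os_, oe in seen[scaffold]:
                if s < oe and os_ < e:
                    raise ValueError(f"overlapping components on {scaffold}")
            seen[scaffold].append((s, e))
    return dict(chains)
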
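"""Synthetic avian-like genomes with planted rearrangements.

The generator produces everything the downstream assembly and breakpoint
analyses consume, together with a ground-truth log, so the whole pipeline is
testable without any external data:

* an ancestral multichromosomal genome (macro- and microchromosomes) carrying
  a CNE track at a configurable genome-wide density and msHSB blocks placed
  at a configurable CNE enrichment;
* planted inversions, fusions and fissions whose breakpoints are sampled with
  a bias towards CNE-poor 1-kb windows;
* fragmentation of the derived karyotype into scaffolds, a configurable
  fraction of which are chimeric (joining distant loci);
* per-junction spanning read-pair ("physical") coverage, Poisson-distributed
  with separate rates for true and chimeric joins;
* an in-silico PCR oracle honoring the testability rule that only junction
  spans below 6 kbp can be assayed;
* a panel of evenly spaced BAC-like markers with their observed hybridization
  order on each derived chromosome.

The CNE landscape is deliberately structured: the genome is tiled into
regulatory "domains" whose CNE intensity is drawn from a mixture containing
CNE deserts, and subtelomeric regions are CNE-poor.  Both features are what
make a CNE-poor breakpoint bias produce depleted breakpoint regions while
flanking windows retain ordinary density, as observed in real avian genomes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .genome import Genome
from .intervals import SeqInterval, as_interval_array, coverage_in_windows, merge_intervals

__all__ = [
    "SimConfig",
    "TruthLog",
    "DerivedKaryotype",
    "Scaffold",
    "AlignmentBlock",
    "BacMarker",
    "generate_ancestor",
    "sample_breakpoint",
    "apply_rearrangements",
    "fragment_and_observe",
    "pcr_oracle",
    "emit_bac_panel",
    "simulate",
    "SimulationResult",
]

WINDOW = 1000  # candidate breakpoint window size (bp)


@dataclass
class SimConfig:
    """Parameters of the synthetic study system.

    Defaults describe a scaled-down avian-like genome: a few large
    macrochromosomes, many small microchromosomes, a CNE track at genome-wide
    density 0.087 with msHSB blocks enriched to 0.107, and a fusion-dominated
    event mix with CNE-poor breakpoint bias.
    """

    n_macro: int = 4
    n_micro: int = 8
    macro_length_range: Tuple[int, int] = (15_000_000, 25_000_000)
    micro_length_range: Tuple[int, int] = (3_000_000, 7_000_000)

    # CNE track
    cne_target_density: float = 0.087
    cne_density_tolerance: float = 0.005
    cne_median_length: int = 100
    cne_sigma_log: float = 0.6
    cne_min_length: int = 20
    cne_max_length: int = 1000

    # regional structure of the CNE landscape
    domain_size: int = 100_000
    desert_fraction: float = 0.15
    desert_intensity: float = 0.05
    telomere_region: int = 200_000
    telomere_intensity: float = 0.15
    telomere_unaligned: int = 10_000  # terminal bp with no usable alignment

    # msHSB track
    mshsb_count: int = 8
    mshsb_length_range: Tuple[int, int] = (1_500_000, 4_000_000)
    mshsb_enrichment: float = 0.107 / 0.087

    # planted events
    n_inversions: int = 20
    n_fusions: int = 12
    n_fissions: int = 8
    breakpoint_bias_gamma: float = 8.0
    gamma_factor_inversion: float = 1.0
    gamma_factor_fission: float = 8.0
    exclude_mshsb_breakpoints: bool = True
    min_inversion_span: int = 700_000
    min_fission_margin: int = 2_000_000

    # fragmentation & observation
    n_scaffolds: int = 150
    chimera_rate: float = 0.10
    chimera_min_separation: int = 1_000_000
    lambda_true: float = 400.0
    lambda_chim: float = 5.0
    junction_gap_scale: float = 5_000.0
    pcr_testable_max_span: int = 6_000
    pcr_error_rate: float = 0.0
    bac_spacing: int = 50_000
    bac_dropout: float = 0.0

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_macro", "n_micro", "n_inversions", "n_fusions",
                     "n_fissions", "n_scaffolds", "mshsb_count"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.breakpoint_bias_gamma < 0:
            raise ValueError("breakpoint_bias_gamma must be >= 0")
        for name in ("chimera_rate", "bac_dropout", "pcr_error_rate"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if not (0.0 <= self.cne_target_density <= 1.0):
            raise ValueError("cne_target_density must lie in [0, 1]")

    def class_gamma(self, event_type: str) -> float:
        g = self.breakpoint_bias_gamma
        return g * {
            "inversion": self.gamma_factor_inversion,
            "fission": self.gamma_factor_fission,
        }[event_type]


@dataclass
class TruthLog:
    """Ground truth for every planted feature of a simulation."""

    events: List[dict] = field(default_factory=list)
    joins: List[dict] = field(default_factory=list)  # intra-scaffold junctions
    bacs: List[dict] = field(default_factory=list)

    def planted_breakpoint_windows(self) -> List[SeqInterval]:
        """Ancestral 1-kb windows in which breakpoints were planted."""
        out = []
        for ev in self.events:
            for chrom, wstart, wend in ev["windows"]:
                out.append(SeqInterval(chrom, wstart, wend))
        return out

    def event_multiset(self) -> Dict[str, int]:
        counts = {"fusion": 0, "fission": 0, "inversion": 0}
        for ev in self.events:
            counts[ev["type"]] += 1
        return counts

    def join_lookup(self) -> Dict[Tuple[str, int], dict]:
        return {(j["scaffold"], j["offset"]): j for j in self.joins}

    def to_json(self) -> str:
        return json.dumps(
            {"events": self.events, "joins": self.joins, "bacs": self.bacs},
            indent=0, sort_keys=True,
        )


@dataclass(frozen=True)
class AlignmentBlock:
    """A colinear mapping between a scaffold segment and the reference."""

    ref_chrom: str
    ref_start: int
    ref_end: int
    scaffold: str
    tgt_start: int
    tgt_end: int
    strand: str  # '+' or '-'


@dataclass
class Scaffold:
    id: str
    length: int


@dataclass(frozen=True)
class BacMarker:
    id: str
    ref: SeqInterval


# ---------------------------------------------------------------------------
# ancestral genome generation


def _place_nonoverlapping(
    rng: np.random.Generator,
    region_start: int,
    region_end: int,
    target_bases: int,
    cfg: SimConfig,
    occupied: List[Tuple[int, int]],
) -> int:
    """Place CNEs in [region_start, region_end) totalling ~target_bases.

    The element count is Poisson so neighboring windows stay uncorrelated
    (a fixed quota would anti-correlate nearby densities).  Appends to
    ``occupied``; returns bases placed.  Overlapping candidates are dropped,
    so placement saturates naturally in crowded regions.
    """
    span = region_end - region_start
    if span <= cfg.cne_min_length or target_bases <= 0:
        return 0
    mean_len = min(
        cfg.cne_median_length * float(np.exp(cfg.cne_sigma_log**2 / 2)),
        float(cfg.cne_max_length),
    )
    n = int(rng.poisson(target_bases / mean_len))
    if n == 0:
        return 0
    lens = np.clip(
        rng.lognormal(np.log(cfg.cne_median_length), cfg.cne_sigma_log, size=n),
        cfg.cne_min_length,
        cfg.cne_max_length,
    ).astype(np.int64)
    lens = lens[lens < span]
    if len(lens) == 0:
        return 0
    starts = rng.integers(region_start, region_end - lens)
    cand = sorted(zip(starts.tolist(), (starts + lens).tolist()))
    merged = sorted(occupied)
    kept: List[Tuple[int, int]] = []
    placed = 0
    ptr = 0
    for s, e in cand:
        if kept and s < kept[-1][1]:
            continue
        while ptr < len(merged) and merged[ptr][1] <= s:
            ptr += 1
        if ptr < len(merged) and merged[ptr][0] < e:
            continue
        kept.append((s, e))
        placed += e - s
    occupied.extend(kept)
    return placed


def generate_ancestor(config: SimConfig, rng: Optional[np.random.Generator] = None) -> Genome:
    """Generate the ancestral genome with CNE and msHSB tracks.

    CNE intensity varies by 100-kb domain (a fraction of domains are CNE
    deserts), subtelomeric regions are CNE-poor, and msHSB blocks carry an
    enriched density.  Placement iterates until the realized genome-wide
    density is within ``cne_density_tolerance`` of the target or placement
    saturates.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if config.cne_target_density > 1.0:
        raise ValueError("infeasible CNE density > 1")

    chroms: Dict[str, int] = {}
    for i in range(config.n_macro):
        lo, hi = config.macro_length_range
        chroms[f"anc{i + 1}"] = int(rng.integers(lo, hi + 1))
    for i in range(config.n_micro):
        lo, hi = config.micro_length_range
        chroms[f"anc{config.n_macro + i + 1}"] = int(rng.integers(lo, hi + 1))
    genome = Genome(chroms)
    if config.cne_target_density == 0.0:
        genome.set_track("CNE", {})
        genome.set_track("msHSB", {})
        return genome

    # msHSB placement: uniform, non-overlapping, away from chromosome ends
    mshsb: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chroms}
    lengths = np.array(list(chroms.values()), dtype=float)
    names = list(chroms)
    placed_blocks = 0
    attempts = 0
    while placed_blocks < config.mshsb_count and attempts < 50 * max(config.mshsb_count, 1):
        attempts += 1
        ci = rng.choice(len(names), p=lengths / lengths.sum())
        chrom = names[ci]
        lo, hi = config.mshsb_length_range
        L = int(rng.integers(lo, hi + 1))
        margin = config.telomere_region
        if chroms[chrom] - 2 * margin <= L:
            continue
        s = int(rng.integers(margin, chroms[chrom] - margin - L))
        e = s + L
        if any(s < oe and os_ < e for os_, oe in mshsb[chrom]):
            continue
        mshsb[chrom].append((s, e))
        placed_blocks += 1
    genome.set_track("msHSB", {c: v for c, v in mshsb.items() if v})

    # density budget: msHSB bases at enriched density, remainder balances out
    g = config.cne_target_density
    h = min(g * config.mshsb_enrichment, 0.9)
    L_tot = genome.total_length
    S = genome.track_total("msHSB")
    rest_density = (g * L_tot - h * S) / (L_tot - S)
    if rest_density < 0:
        raise ValueError("infeasible CNE density given msHSB enrichment")

    cne: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chroms}
    for chrom, length in chroms.items():
        hsb = mshsb[chrom]
        # domain-level intensity multipliers for non-msHSB sequence
        n_dom = max(1, length // config.domain_size)
        edges = np.linspace(0, length, n_dom + 1).astype(np.int64)
        mult = np.where(
            rng.random(n_dom) < config.desert_fraction,
            config.desert_intensity,
            (1.0 - config.desert_fraction * config.desert_intensity)
            / (1.0 - config.desert_fraction),
        )
        occupied: List[Tuple[int, int]] = []
        for di in range(n_dom):
            ds, de = int(edges[di]), int(edges[di + 1])
            # subtelomeric damping
            m = mult[di]
            if ds < config.telomere_region or de > length - config.telomere_region:
                m = config.telomere_intensity
            # carve out msHSB overlap; msHSBs are filled separately below
            pieces = [(ds, de)]
            for hs, he in hsb:
                pieces = [
                    p
                    for seg in pieces
                    for p in ((seg[0], min(seg[1], hs)), (max(seg[0], he), seg[1]))
                    if p[0] < p[1]
                ]
            for ps, pe in pieces:
                _place_nonoverlapping(
                    rng, ps, pe, int(m * rest_density * (pe - ps)), config, occupied
                )
        for hs, he in hsb:
            _place_nonoverlapping(rng, hs, he, int(h * (he - hs)), config, occupied)
        cne[chrom] = occupied

    genome.set_track("CNE", {c: merge_intervals(as_interval_array(v)) for c, v in cne.items() if v})

    # top-up loop towards the genome-wide target
    for _ in range(20):
        realized = genome.track_density("CNE")
        if abs(realized - g) <= config.cne_density_tolerance:
            break
        deficit = int((g - realized) * L_tot)
        if deficit <= 0:
            break
        chrom = names[int(rng.choice(len(names), p=lengths / lengths.sum()))]
        extra: List[Tuple[int, int]] = [tuple(x) for x in genome.track("CNE", chrom)]
        _place_nonoverlapping(
            rng,
            config.telomere_region,
            chroms[chrom] - config.telomere_region,
            min(deficit, chroms[chrom] // 50),
            config,
            extra,
        )
        genome.set_track(
            "CNE",
            {
                **{c: genome.track("CNE", c) for c in genome.tracks.get("CNE", {})},
                chrom: merge_intervals(as_interval_array(extra)),
            },
        )
    return genome


# ---------------------------------------------------------------------------
# breakpoint sampling


def _window_weights(
    genome: Genome, gamma: float, exclude_mshsb: bool = False
) -> Dict[str, np.ndarray]:
    """Per-chromosome sampling weight (1 - cne_fraction)**gamma per window."""
    weights: Dict[str, np.ndarray] = {}
    for chrom in genome.chromosomes:
        bases = genome.window_track_bases("CNE", chrom, WINDOW)
        w = np.power(1.0 - bases / WINDOW, gamma)
        if exclude_mshsb:
            hsb = genome.window_track_bases("msHSB", chrom, WINDOW)
            w = np.where(hsb > 0, 0.0, w)
        weights[chrom] = w
    return weights


def sample_breakpoint(
    genome: Genome,
    gamma: float,
    rng: np.random.Generator,
    exclude_mshsb: bool = False,
) -> Tuple[str, int]:
    """Sample a breakpoint position biased towards CNE-poor windows.

    The genome is tiled into 1-kb candidate windows; a window is chosen with
    probability proportional to ``(1 - cne_fraction)**gamma`` and the
    position is then uniform within the window.
    """
    weights = _window_weights(genome, gamma, exclude_mshsb)
    chroms = list(weights)
    totals = np.array([w.sum() for w in weights.values()])
    if totals.sum() <= 0:
        raise ValueError("all candidate windows have zero weight")
    ci = rng.choice(len(chroms), p=totals / totals.sum())
    chrom = chroms[ci]
    w = weights[chrom]
    wi = rng.choice(len(w), p=w / w.sum())
    pos = int(wi * WINDOW + rng.integers(0, WINDOW))
    return chrom, pos


# ---------------------------------------------------------------------------
# the derived karyotype


class DerivedKaryotype:
    """A karyotype expressed as signed segment chains over the ancestor.

    Each derived chromosome is an ordered list of ``(anc_chrom, start, end,
    orient)`` segments with ``orient`` +1 or -1.  All tracks stay in ancestral
    coordinates; queries on derived intervals are answered by pulling the
    interval back through the segment map.
    """

    def __init__(self, ancestor: Genome):
        self.ancestor = ancestor
        self.chromosomes: Dict[str, List[Tuple[str, int, int, int]]] = {
            c: [(c, 0, length, 1)] for c, length in ancestor.chromosomes.items()
        }
        self._counter = 0

    def chrom_length(self, chrom: str) -> int:
        return sum(e - s for _, s, e, _ in self.chromosomes[chrom])

    @property
    def total_length(self) -> int:
        return sum(self.chrom_length(c) for c in self.chromosomes)

    def _new_name(self) -> str:
        self._counter += 1
        return f"der{self._counter}"

    # -- coordinate mapping -------------------------------------------------

    def map_to_ancestor(
        self, chrom: str, start: int, end: int
    ) -> List[Tuple[str, int, int, int]]:
        """Pull a derived interval back to ancestral segments, in derived order."""
        if not (0 <= start < end <= self.chrom_length(chrom)):
            raise ValueError("interval outside derived chromosome")
        out = []
        offset = 0
        for anc, s, e, o in self.chromosomes[chrom]:
            seg_len = e - s
            lo = max(start, offset)
            hi = min(end, offset + seg_len)
            if lo < hi:
                if o == 1:
                    out.append((anc, s + (lo - offset), s + (hi - offset), 1))
                else:
                    out.append((anc, e - (hi - offset), e - (lo - offset), -1))
            offset += seg_len
        return out

    def ancestor_position(self, anc_chrom: str, pos: int) -> Optional[Tuple[str, int]]:
        """Derived location of an ancestral base, or None if not present."""
        loc = self.locate_ancestor(anc_chrom, pos)
        if loc is None:
            return None
        return loc[0], loc[1]

    def locate_ancestor(self, anc_chrom: str, pos: int):
        """(derived_chrom, derived_pos, segment_index, seg_dstart, seg_dend,
        orient) for an ancestral base, or None."""
        for chrom, segs in self.chromosomes.items():
            offset = 0
            for i, (anc, s, e, o) in enumerate(segs):
                if anc == anc_chrom and s <= pos < e:
                    dpos = offset + (pos - s) if o == 1 else offset + (e - 1 - pos)
                    return chrom, dpos, i, offset, offset + (e - s), o
                offset += e - s
        return None

    def units_present(self, chrom: str) -> set:
        return {anc for anc, _s, _e, _o in self.chromosomes[chrom]}

    def derived_to_ancestor_point(self, chrom: str, pos: int) -> Tuple[str, int]:
        segs = self.map_to_ancestor(chrom, pos, pos + 1)
        anc, s, _e, _o = segs[0]
        return anc, s

    # -- rearrangement operators --------------------------------------------

    def fission(self, chrom: str, pos: int) -> Tuple[str, str]:
        length = self.chrom_length(chrom)
        if not (0 < pos < length):
            raise ValueError("fission position must be internal")
        left = self.map_to_ancestor(chrom, 0, pos)
        right = self.map_to_ancestor(chrom, pos, length)
        a, b = self._new_name(), self._new_name()
        del self.chromosomes[chrom]
        self.chromosomes[a] = left
        self.chromosomes[b] = right
        return a, b

    def fusion(self, chrom_a: str, chrom_b: str, flip_b: bool) -> str:
        if chrom_a == chrom_b:
            raise ValueError("fusion requires two distinct chromosomes")
        segs_a = self.chromosomes[chrom_a]
        segs_b = self.chromosomes[chrom_b]
        if flip_b:
            segs_b = [(anc, s, e, -o) for anc, s, e, o in reversed(segs_b)]
        name = self._new_name()
        del self.chromosomes[chrom_a]
        del self.chromosomes[chrom_b]
        self.chromosomes[name] = segs_a + segs_b
        return name

    def inversion(self, chrom: str, start: int, end: int) -> None:
        length = self.chrom_length(chrom)
        if not (0 <= start < end <= length):
            raise ValueError("invalid inversion span")
        left = self.map_to_ancestor(chrom, 0, start) if start > 0 else []
        mid = self.map_to_ancestor(chrom, start, end)
        right = self.map_to_ancestor(chrom, end, length) if end < length else []
        mid = [(anc, s, e, -o) for anc, s, e, o in reversed(mid)]
        self.chromosomes[chrom] = left + mid + right

    # -- track pull-backs ----------------------------------------------------

    def cne_bases_in(self, chrom: str, start: int, end: int, track: str = "CNE") -> int:
        total = 0
        for anc, s, e, _o in self.map_to_ancestor(chrom, start, end):
            arr = self.ancestor.track(track, anc)
            total += int(coverage_in_windows(arr, np.asarray([s, e]))[0])
        return total

    def copy(self) -> "DerivedKaryotype":
        k = DerivedKaryotype(self.ancestor)
        k.chromosomes = {c: list(v) for c, v in self.chromosomes.items()}
        k._counter = self._counter
        return k


# ---------------------------------------------------------------------------
# planted rearrangements


SEGMENT_MARGIN = 250_000  # min distance of a planted cut from existing segment boundaries


class _WeightSampler:
    """Inverse-CDF sampler over per-chromosome window weights."""

    def __init__(self, weights: Dict[str, np.ndarray]):
        self.chroms = [c for c, w in weights.items() if w.sum() > 0]
        if not self.chroms:
            raise ValueError("all candidate windows have zero weight")
        self.cums = {c: np.cumsum(weights[c]) for c in self.chroms}
        self.totals = np.cumsum([self.cums[c][-1] for c in self.chroms])

    def draw(self, rng: np.random.Generator) -> Tuple[str, int]:
        u = rng.random() * self.totals[-1]
        ci = int(np.searchsorted(self.totals, u, side="right"))
        ci = min(ci, len(self.chroms) - 1)
        chrom = self.chroms[ci]
        rem = u - (self.totals[ci - 1] if ci > 0 else 0.0)
        wi = int(np.searchsorted(self.cums[chrom], rem, side="right"))
        wi = min(wi, len(self.cums[chrom]) - 1)
        return chrom, wi


def _sample_mapped_breakpoint(
    kary: DerivedKaryotype,
    sampler: "_WeightSampler",
    rng: np.random.Generator,
    accept,
    max_tries: int = 4000,
):
    """Sample ancestral windows by weight until the derived image satisfies
    ``accept(location_tuple)`` (see :meth:`DerivedKaryotype.locate_ancestor`).

    Returns (location, ancestral_window).
    """
    for _ in range(max_tries):
        anc, wi = sampler.draw(rng)
        pos = int(wi * WINDOW + rng.integers(0, WINDOW))
        loc = kary.locate_ancestor(anc, pos)
        if loc is None:
            continue
        if accept(loc):
            return loc, (anc, wi * WINDOW, (wi + 1) * WINDOW)
    raise RuntimeError("could not sample a feasible breakpoint")


def apply_rearrangements(
    genome: Genome,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[DerivedKaryotype, TruthLog]:
    """Apply the configured numbers of fusions, fissions and inversions.

    Events are applied as fissions, then fusions, then inversions: fissions
    cut pristine chromosomes, fusions join products without ever rejoining
    pieces of one ancestral unit, and each inversion reverses a span inside
    a single colinear segment.  This keeps every planted event separately
    identifiable in the final karyotype (the planted multiset equals what a
    correct homology-map analysis recovers).  Fission and inversion
    breakpoints are sampled with the CNE-poor window bias; fusions join two
    chromosome ends (the flanking terminal windows are recorded as the
    breakpoint regions).  Total sequence length and all track bases are
    conserved by construction since every operator is a permutation of
    ancestral segments.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    kary = DerivedKaryotype(genome)
    truth = TruthLog()
    n_chroms = len(genome.chromosomes)
    if config.n_fusions > n_chroms + config.n_fissions - 1:
        raise ValueError("more fusions than available chromosome pairs")

    events = (
        ["fission"] * config.n_fissions
        + ["fusion"] * config.n_fusions
        + ["inversion"] * config.n_inversions
    )

    raw_weights = {
        t: _window_weights(genome, config.class_gamma(t), config.exclude_mshsb_breakpoints)
        for t in ("inversion", "fission")
    }
    weights_by_type = {t: _WeightSampler(w) for t, w in raw_weights.items()}

    sm = SEGMENT_MARGIN

    for ev in events:
        if ev == "fission":
            margin = config.min_fission_margin

            def ok_fission(loc):
                dchrom, dpos, _i, seg_s, seg_e, orient = loc
                if orient != 1:
                    # cut only forward segments so each product stays colinear
                    return False
                L = kary.chrom_length(dchrom)
                m = min(margin, max(L // 4, 1))
                s = min(sm, max((seg_e - seg_s) // 3, 1))
                return (
                    m <= dpos <= L - m
                    and seg_s + s <= dpos <= seg_e - s
                )

            loc, window = _sample_mapped_breakpoint(
                kary, weights_by_type["fission"], rng, ok_fission
            )
            dchrom, dpos = loc[0], loc[1]
            anc_pt = kary.derived_to_ancestor_point(dchrom, dpos)
            a, b = kary.fission(dchrom, dpos)
            truth.events.append(
                {
                    "type": "fission",
                    "breakpoints": [list(anc_pt)],
                    "windows": [list(window)],
                    "derived": [a, b],
                }
            )
        elif ev == "fusion":
            # never rejoin two chromosomes sharing an ancestral unit: pieces
            # of a fissioned chromosome stay apart, so the planted event
            # multiset remains identifiable from the final homology map
            names = list(kary.chromosomes)
            if len(names) < 2:
                raise ValueError("fusion infeasible: fewer than two chromosomes")
            for _try in range(200):
                ia, ib = rng.choice(len(names), size=2, replace=False)
                ca, cb = names[ia], names[ib]
                if not (kary.units_present(ca) & kary.units_present(cb)):
                    break
            else:
                raise RuntimeError("no fusion pair without shared ancestral units")
            flip = bool(rng.integers(0, 2))
            end_a = kary.derived_to_ancestor_point(ca, kary.chrom_length(ca) - 1)
            start_b = (
                kary.derived_to_ancestor_point(cb, kary.chrom_length(cb) - 1)
                if flip
                else kary.derived_to_ancestor_point(cb, 0)
            )
            windows = []
            for anc, pos in (end_a, start_b):
                w0 = (pos // WINDOW) * WINDOW
                w1 = min(w0 + WINDOW, genome.chromosomes[anc])
                windows.append([anc, w0, max(w1, w0 + 1)])
            name = kary.fusion(ca, cb, flip)
            truth.events.append(
                {
                    "type": "fusion",
                    "breakpoints": [list(end_a), list(start_b)],
                    "windows": windows,
                    "derived": [name],
                }
            )
        else:  # inversion: the reversed span stays inside one ancestral segment
            span = config.min_inversion_span
            done = False
            for _try in range(200):
                def ok_first(loc):
                    _d, dpos, _i, seg_s, seg_e, _o = loc
                    return (
                        seg_e - seg_s >= span + 2 * sm
                        and seg_s + sm <= dpos <= seg_e - sm
                    )

                loc1, w1 = _sample_mapped_breakpoint(
                    kary, weights_by_type["inversion"], rng, ok_first
                )
                d1, p1, seg_i, seg_s, seg_e, _seg_o = loc1
                anc, a_lo, a_hi, a_o = kary.chromosomes[d1][seg_i]
                a1 = kary.derived_to_ancestor_point(d1, p1)[1]
                # second breakpoint: sample directly from the weight profile
                # restricted to the same ancestral segment, far enough away
                w = raw_weights["inversion"][anc]
                idx = np.arange(len(w))
                centers = idx * WINDOW + WINDOW // 2
                allowed = (
                    (idx * WINDOW >= a_lo + sm)
                    & ((idx + 1) * WINDOW <= a_hi - sm)
                    & (np.abs(centers - a1) >= span + WINDOW)
                )
                wa = np.where(allowed, w, 0.0)
                if wa.sum() <= 0:
                    continue
                cum = np.cumsum(wa)
                wi = int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))
                wi = min(wi, len(w) - 1)
                a2 = int(wi * WINDOW + rng.integers(0, WINDOW))
                w2 = (anc, wi * WINDOW, (wi + 1) * WINDOW)
                if a_o == 1:
                    p2 = seg_s + (a2 - a_lo)
                else:
                    p2 = seg_s + (a_hi - 1 - a2)
                done = True
                break
            if not done:
                raise RuntimeError("could not place inversion")
            lo, hi = min(p1, p2), max(p1, p2)
            bp1 = kary.derived_to_ancestor_point(d1, lo)
            bp2 = kary.derived_to_ancestor_point(d1, hi)
            kary.inversion(d1, lo, hi)
            truth.events.append(
                {
                    "type": "inversion",
                    "breakpoints": [list(bp1), list(bp2)],
                    "windows": [list(w1), list(w2)],
                    "derived": [d1],
                }
            )
    return kary, truth


# ---------------------------------------------------------------------------
# fragmentation, alignment blocks, coverage


def fragment_and_observe(
    kary: DerivedKaryotype,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
    truth: Optional[TruthLog] = None,
) -> Tuple[List[Scaffold], List[AlignmentBlock], List[Tuple[str, int, int]], TruthLog]:
    """Cut the karyotype into scaffolds and emit the observable evidence.

    Returns (scaffolds, alignment blocks, coverage table, truth).  Coverage
    rows are ``(scaffold_id, junction_offset, spanning_pairs)``.  With
    probability ``chimera_rate`` a scaffold is made chimeric by concatenating
    a fragment from a distant locus (different chromosome or >= 1 Mb away).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if truth is None:
        truth = TruthLog()
    chrom_names = list(kary.chromosomes)
    if config.n_scaffolds < len(chrom_names):
        raise ValueError("n_scaffolds must be >= number of derived chromosomes")

    total = kary.total_length
    fragments: List[Tuple[str, int, int]] = []
    remaining = config.n_scaffolds - len(chrom_names)
    for chrom in chrom_names:
        L = kary.chrom_length(chrom)
        extra = int(round(remaining * L / max(total, 1)))
        cuts = np.sort(rng.integers(1, L, size=extra)) if extra > 0 else np.array([], dtype=int)
        edges = np.unique(np.concatenate([[0], cuts, [L]]))
        for s, e in zip(edges[:-1], edges[1:]):
            fragments.append((chrom, int(s), int(e)))

    def far_apart(f1, f2) -> bool:
        if f1[0] != f2[0]:
            return True
        gap = max(f1[1], f2[1]) - min(f1[2], f2[2])
        return gap >= config.chimera_min_separation

    order = list(rng.permutation(len(fragments)))
    used = set()
    scaffold_pieces: List[List[Tuple[str, int, int, int]]] = []
    chimeric_flags: List[bool] = []
    for idx in order:
        if idx in used:
            continue
        used.add(idx)
        frag = fragments[idx]
        pieces = [(frag[0], frag[1], frag[2], 1)]
        chim = False
        if rng.random() < config.chimera_rate:
            partners = [
                j for j in order
                if j not in used and far_apart(fragments[j], frag)
            ]
            if partners:
                j = partners[int(rng.integers(0, len(partners)))]
                used.add(j)
                other = fragments[j]
                o = 1 if rng.random() < 0.5 else -1
                pieces.append((other[0], other[1], other[2], o))
                chim = True
        if rng.random() < 0.5:  # scaffolds have arbitrary sign
            pieces = [(c, s, e, -o) for c, s, e, o in reversed(pieces)]
        scaffold_pieces.append(pieces)
        chimeric_flags.append(chim)

    scaffolds: List[Scaffold] = []
    blocks: List[AlignmentBlock] = []
    coverage: List[Tuple[str, int, int]] = []

    for si, (pieces, chim) in enumerate(zip(scaffold_pieces, chimeric_flags)):
        sid = f"scaf{si + 1}"
        length = sum(e - s for _, s, e, _ in pieces)
        scaffolds.append(Scaffold(sid, length))

        # expand pieces into ancestral blocks in scaffold order
        raw: List[Tuple[str, int, int, int, bool]] = []  # (+ is_piece_boundary)
        for pi, (chrom, s, e, o) in enumerate(pieces):
            segs = kary.map_to_ancestor(chrom, s, e)
            if o == -1:
                segs = [(a, ss, ee, -oo) for a, ss, ee, oo in reversed(segs)]
            for bi, (a, ss, ee, oo) in enumerate(segs):
                raw.append((a, ss, ee, oo, pi > 0 and bi == 0))

        # alignment losses per block side, in scaffold bp: subtelomeric
        # sequence never aligns, and every junction loses an exponential gap
        t_un = config.telomere_unaligned
        anc_len = kary.ancestor.chromosomes
        n = len(raw)
        blens = [ee - ss for _a, ss, ee, _o, _p in raw]
        offsets = [0]
        for b in blens:
            offsets.append(offsets[-1] + b)
        cut_front = [0] * n  # removed at the tgt-start side of block i
        cut_back = [0] * n  # removed at the tgt-end side
        for i, (anc, ss, ee, oo, _ps) in enumerate(raw):
            L = anc_len[anc]
            lo = max(min(t_un, L // 4) - ss, 0)  # unalignable at ancestral start
            hi = max(ee - (L - min(t_un, L // 4)), 0)
            lo, hi = min(lo, blens[i]), min(hi, blens[i])
            if oo == 1:
                cut_front[i], cut_back[i] = lo, hi
            else:
                cut_front[i], cut_back[i] = hi, lo

        for bi in range(1, n):
            is_chimeric = raw[bi][4] and chim
            gap = int(rng.exponential(config.junction_gap_scale))
            avail_prev = blens[bi - 1] - cut_front[bi - 1] - cut_back[bi - 1]
            avail_cur = blens[bi] - cut_front[bi] - cut_back[bi]
            trim_left = max(min(gap // 2, avail_prev - 1), 0)
            trim_right = max(min(gap - gap // 2, avail_cur - 1), 0)
            cut_back[bi - 1] += trim_left
            cut_front[bi] += trim_right
            span = cut_back[bi - 1] + cut_front[bi]
            lam = config.lambda_chim if is_chimeric else config.lambda_true
            cov = int(rng.poisson(lam))
            coverage.append((sid, int(offsets[bi]), cov))
            truth.joins.append(
                {
                    "scaffold": sid,
                    "offset": int(offsets[bi]),
                    "chimeric": bool(is_chimeric),
                    "span": int(span),
                    "coverage": cov,
                }
            )

        for i, (anc, ss, ee, oo, _ps) in enumerate(raw):
            f, b = cut_front[i], cut_back[i]
            if blens[i] - f - b <= 0:
                continue  # block entirely unalignable
            tgt_s, tgt_e = offsets[i] + f, offsets[i + 1] - b
            if oo == 1:
                blocks.append(AlignmentBlock(anc, ss + f, ee - b, sid, tgt_s, tgt_e, "+"))
            else:
                blocks.append(AlignmentBlock(anc, ss + b, ee - f, sid, tgt_s, tgt_e, "-"))
    return scaffolds, blocks, coverage, truth


# ---------------------------------------------------------------------------
# in-silico wet lab


def pcr_oracle(
    join: Tuple[str, int],
    truth: TruthLog,
    rng: Optional[np.random.Generator] = None,
    max_span: int = 6_000,
    error_rate: float = 0.0,
) -> str:
    """PCR outcome for an intra-scaffold junction.

    Junctions whose unaligned span is >= 6 kbp cannot be assayed (primer
    design fails) and return ``"untestable"``; otherwise the outcome reflects
    the planted truth, optionally flipped at ``error_rate``.
    """
    rec = truth.join_lookup().get((join[0], int(join[1])))
    if rec is None:
        raise KeyError(f"unknown junction {join!r}")
    if rec["span"] >= max_span:
        return "untestable"
    outcome = "refuted" if rec["chimeric"] else "confirmed"
    if error_rate > 0 and rng is not None and rng.random() < error_rate:
        outcome = "confirmed" if outcome == "refuted" else "refuted"
    return outcome


def emit_bac_panel(
    kary: DerivedKaryotype,
    spacing: int,
    rng: Optional[np.random.Generator] = None,
    dropout: float = 0.0,
    truth: Optional[TruthLog] = None,
) -> Tuple[List[BacMarker], List[Tuple[str, str, int]]]:
    """Place markers every ~spacing bp on the ancestor and observe their
    hybridization order on the derived chromosomes.

    Returns (markers, observations) where an observation is
    ``(bac_id, derived_chrom, order_index)``.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    anc = kary.ancestor
    if spacing > max(anc.chromosomes.values()):
        raise ValueError("spacing larger than every chromosome")
    if rng is None:
        rng = np.random.default_rng(0)
    markers: List[BacMarker] = []
    hits: List[Tuple[str, int, str]] = []  # derived chrom, derived pos, bac id
    for chrom, length in anc.chromosomes.items():
        pos = spacing // 2
        i = 0
        while pos + 1 <= length:
            bid = f"BAC_{chrom}_{i}"
            if dropout > 0 and rng.random() < dropout:
                pos += spacing
                i += 1
                continue
            markers.append(BacMarker(bid, SeqInterval(chrom, pos, pos + 1)))
            loc = kary.ancestor_position(chrom, pos)
            if loc is not None:
                hits.append((loc[0], loc[1], bid))
            if truth is not None:
                truth.bacs.append({"id": bid, "ref": [chrom, pos], "derived": list(loc) if loc else None})
            pos += spacing
            i += 1
    observations: List[Tuple[str, str, int]] = []
    by_chrom: Dict[str, List[Tuple[int, str]]] = {}
    for dchrom, dpos, bid in hits:
        by_chrom.setdefault(dchrom, []).append((dpos, bid))
    for dchrom, lst in by_chrom.items():
        for rank, (_pos, bid) in enumerate(sorted(lst)):
            observations.append((bid, dchrom, rank))
    return markers, observations


# ---------------------------------------------------------------------------
# one-call simulation bundle


@dataclass
class SimulationResult:
    config: SimConfig
    ancestor: Genome
    karyotype: DerivedKaryotype
    truth: TruthLog
    scaffolds: List[Scaffold]
    blocks: List[AlignmentBlock]
    coverage: List[Tuple[str, int, int]]
    bacs: List[BacMarker]
    observations: List[Tuple[str, str, int]]


def simulate(config: SimConfig) -> SimulationResult:
    """Run ancestor generation, rearrangement, fragmentation and observation
    with stage-separated deterministic random streams."""
    ss = np.random.SeedSequence(config.seed)
    r_anc, r_evt, r_frag, r_bac = [np.random.default_rng(s) for s in ss.spawn(4)]
    ancestor = generate_ancestor(config, r_anc)
    kary, truth = apply_rearrangements(ancestor, config, r_evt)
    scaffolds, blocks, coverage, truth = fragment_and_observe(kary, config, r_frag, truth)
    bacs, obs = emit_bac_panel(kary, config.bac_spacing, r_bac, config.bac_dropout, truth)
    return SimulationResult(
        config, ancestor, kary, truth, scaffolds, blocks, coverage, bacs, obs
    )
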
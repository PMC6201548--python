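"""Replicated in-silico experiments over the simulator and analysis stack.

Each function runs one seeded trial (or a batch of them) of a property the
package is expected to reproduce: exact recovery of planted rearrangements
through the full assembly pipeline, recovery of the spanning-coverage split
threshold from PCR outcomes, the CNE-density ordering of breakpoint classes,
the flank-depletion contrast, and the type-I error of the flank test under
an unbiased breakpoint model.

Problem sizes here are deliberately desk-scale (tens of megabases, tens of
events); the methods note discusses what they do and do not establish.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .assembly import AssemblyParams, Join, assemble_pcfs, build_syntenic_fragments, calibrate_threshold
from .cne import ebr_flank_contrast, scan_1kb_windows
from .fish import anchor, locate_bacs_on_pcfs
from .homology import (
    EBR,
    HomologyMap,
    HomologySegment,
    build_homology_map,
    count_interchromosomal_events,
    detect_ebrs,
    estimate_map_inversions,
)
from .simulate import SimConfig, generate_ancestor, simulate

__all__ = [
    "truth_homology_map",
    "planted_recovery_trial",
    "calibration_trial",
    "class_ordering_trial",
    "flank_depletion_trial",
    "type1_error_trial",
    "RECOVERY_SIM",
    "ORDERING_SIM",
    "DEPLETION_SIM",
]


def truth_homology_map(kary, telomere_unaligned: int = 0) -> HomologyMap:
    """The exact homology map implied by a derived karyotype.

    With ``telomere_unaligned`` > 0, segment reference coordinates are
    clipped by that many bases at ancestral chromosome ends, mirroring what
    an alignment-derived map can see (telomeric sequence never aligns).
    """
    t = telomere_unaligned
    segments: Dict[str, List[HomologySegment]] = {}
    for chrom, segs in kary.chromosomes.items():
        tpos = 0
        lst = []
        for anc, s, e, o in segs:
            L = kary.ancestor.chromosomes[anc]
            cs, ce = max(s, t), min(e, L - t)
            if cs < ce:
                lst.append(
                    HomologySegment(
                        tgt_chrom=chrom, unit=anc, strand="+" if o == 1 else "-",
                        tgt_start=tpos, tgt_end=tpos + (ce - cs),
                        ref_start=cs, ref_end=ce,
                    )
                )
            tpos += e - s
        segments[chrom] = lst
    return HomologyMap(segments=segments)


# conditions for the replicate studies (chosen a priori for statistical
# resolution at desk scale; see docs/methods.md)
RECOVERY_SIM = SimConfig(chimera_rate=0.0)
ORDERING_SIM = SimConfig(n_inversions=24, n_fusions=16, n_fissions=12)
# flank-contrast EBR sets are intrachromosomally dominated, as in real avian
# comparisons where intra EBRs far outnumber interchromosomal ones
DEPLETION_SIM = SimConfig(n_inversions=25, n_fusions=6, n_fissions=5)


def snap_to_windows(ebrs: Sequence[EBR], genome, window: int = 1000) -> List[EBR]:
    """Widen each EBR interval to the enclosing 1-kb window grid.

    Breakpoint intervals from an exact homology map can be arbitrarily
    narrow; all density analyses operate at window resolution, so the
    breakpoint region is its enclosing window(s)."""
    out = []
    for e in ebrs:
        L = genome.chromosomes[e.unit]
        start = (e.start // window) * window
        end = min(-(-e.end // window) * window, L)
        if end <= start:
            continue
        out.append(
            EBR(unit=e.unit, start=start, end=end, cls=e.cls, species=e.species,
                flanks=e.flanks, excluded_from_cne=(end - start) > 100_000)
        )
    return out


def planted_recovery_trial(seed: int, sim: Optional[SimConfig] = None) -> dict:
    """Run simulate -> assemble -> anchor -> homology on chimera-free data
    and compare recovered events with the planted truth.

    Returns a dict with the recovered/planted event counts, whether the
    multiset matches exactly, the fraction of SF-covered length placed, and
    whether every placed fragment is oriented.
    """
    sim = dataclasses.replace(sim or RECOVERY_SIM, seed=seed, chimera_rate=0.0)
    res = simulate(sim)
    params = AssemblyParams()
    sfs = build_syntenic_fragments(res.blocks, params)
    pcfs, _splits = assemble_pcfs(res.scaffolds, sfs, res.coverage, params)
    locations, unmapped = locate_bacs_on_pcfs(res.bacs, sfs, pcfs)
    observations = [ob for ob in res.observations if ob[0] in locations or ob[0] in unmapped]
    assemblies, _dis = anchor(pcfs, locations, observations, policy="split", unmapped=unmapped)
    chains = {c: a.member_chain() for c, a in assemblies.items()}
    hmap = build_homology_map(chains, sfs)
    counts = count_interchromosomal_events(hmap)
    inv = int(estimate_map_inversions(hmap))
    planted = res.truth.event_multiset()

    sf_total = sum(p.length for p in pcfs)
    placed = sum(a.placed_length for a in assemblies.values())
    oriented_ok = all(
        u.strand != "?" and all(m.strand != "?" for m in u.members)
        for a in assemblies.values()
        for u in a.units
    )
    return {
        "recovered": {
            "fusions": counts.fusions,
            "fissions": counts.fissions,
            "inversions": inv,
        },
        "planted": planted,
        "exact": (
            counts.fusions == planted["fusion"]
            and counts.fissions == planted["fission"]
            and inv == planted["inversion"]
            and counts.identity_holds()
        ),
        "pct_sf_placed": 100.0 * placed / sf_total if sf_total else 0.0,
        "all_oriented": oriented_ok,
    }


def calibration_trial(
    seed: int,
    n_joins: int = 30,
    lambda_true: float = 400.0,
    lambda_chim: float = 5.0,
) -> dict:
    """Draw PCR-tested conflicting joins from the two Poisson coverage
    regimes and calibrate the split threshold against the (perfect) PCR
    outcomes.

    Returns the chosen threshold, whether it separates the regimes
    (lambda_chim < T <= lambda_true), and the achieved agreement.
    """
    rng = np.random.default_rng(seed)
    joins: List[Join] = []
    pcr: Dict[Tuple[str, int], str] = {}
    for i in range(n_joins):
        chim = bool(rng.random() < 0.5)
        cov = int(rng.poisson(lambda_chim if chim else lambda_true))
        j = Join(
            scaffold=f"s{i}", left_index=0, right_index=1,
            gap_start=0, gap_end=1, conflict=True, reason="synthetic",
            offset=i, coverage=cov,
        )
        joins.append(j)
        pcr[(j.scaffold, j.offset)] = "refuted" if chim else "confirmed"
    cal = calibrate_threshold(joins, pcr)
    return {
        "threshold": cal.threshold,
        "agreement": cal.agreement,
        "tested": cal.tested,
        "separates": lambda_chim < cal.threshold <= lambda_true,
        "perfect": cal.agreement == cal.tested,
    }


def class_ordering_trial(seed: int, sim: Optional[SimConfig] = None) -> dict:
    """Simulate a rearranged genome, detect EBRs from the exact homology
    map, scan 1-kb windows, and report the class mean densities.

    The qualitative expectation under the CNE-poor breakpoint bias is
    msHSB > genome-wide > intrachromosomal > fusion > fission.
    """
    sim = dataclasses.replace(sim or ORDERING_SIM, seed=seed)
    ss = np.random.SeedSequence(seed)
    r_anc, r_evt = [np.random.default_rng(s) for s in ss.spawn(2)]
    from .simulate import apply_rearrangements  # local import to keep namespace tidy

    genome = generate_ancestor(sim, r_anc)
    kary, _truth = apply_rearrangements(genome, sim, r_evt)
    hmap = truth_homology_map(kary, sim.telomere_unaligned)
    ebrs = snap_to_windows(detect_ebrs(hmap, ref_lengths=genome.chromosomes), genome)
    scan = scan_1kb_windows(genome, ebrs)
    m = scan.class_mean_density
    ordered = (
        m["msHSB"] > scan.genome_mean_density
        and scan.genome_mean_density > m["intrachromosomal"]
        and m["intrachromosomal"] > m["fusion"]
        and m["fusion"] > m["fission"]
    )
    return {
        "class_mean_density": m,
        "genome_mean_density": scan.genome_mean_density,
        "ordered": bool(ordered),
    }


def flank_depletion_trial(
    seed: int, sim: Optional[SimConfig] = None, n_ebrs: int = 60
) -> dict:
    """Planted-depletion contrast: EBR windows vs their four flanks.

    EBRs come from the exact homology map of a biased simulation; the
    one-sided Mann-Whitney U tests EBR density < flank density.
    """
    sim = dataclasses.replace(sim or DEPLETION_SIM, seed=seed)
    ss = np.random.SeedSequence(seed)
    r_anc, r_evt = [np.random.default_rng(s) for s in ss.spawn(2)]
    from .simulate import apply_rearrangements

    genome = generate_ancestor(sim, r_anc)
    kary, _truth = apply_rearrangements(genome, sim, r_evt)
    hmap = truth_homology_map(kary, sim.telomere_unaligned)
    ebrs = [e for e in snap_to_windows(detect_ebrs(hmap, ref_lengths=genome.chromosomes), genome)
            if not e.excluded_from_cne][:n_ebrs]
    report = ebr_flank_contrast(ebrs, genome, alternative="less")
    return {
        "n_ebrs": report.n_ebrs,
        "p_less": report.mannwhitney[1],
        "kruskal_p": report.kruskal[1],
        "ebr_mean": report.group_means["EBR"],
        "flank_mean": float(
            np.mean([v for k, vs in report.group_values.items() if k != "EBR" for v in vs])
        ),
    }


def type1_error_trial(
    seed: int,
    n_reps: int = 200,
    n_ebrs: int = 60,
    ebr_len: int = 2_000,
    alpha: float = 0.05,
) -> dict:
    """Type-I error of the flank contrast under an unbiased breakpoint model.

    Breakpoint intervals are placed uniformly (the gamma = 0 case) on a
    genome with a spatially homogeneous CNE field, so EBR and flank windows
    share one distribution; the two-sided Mann-Whitney rejection rate at
    ``alpha`` should be close to nominal.
    """
    uniform_sim = SimConfig(
        n_macro=2, n_micro=0,
        macro_length_range=(10_000_000, 12_000_000),
        desert_fraction=0.0, telomere_intensity=1.0,
        mshsb_count=0, seed=seed,
    )
    ss = np.random.SeedSequence(seed)
    rejections = 0
    for rep, child in enumerate(ss.spawn(n_reps)):
        rng = np.random.default_rng(child)
        genome = generate_ancestor(dataclasses.replace(uniform_sim, seed=seed + rep), rng)
        ebrs = []
        chroms = list(genome.chromosomes)
        lengths = np.array([genome.chromosomes[c] for c in chroms], dtype=float)
        p = lengths / lengths.sum()
        for _ in range(n_ebrs):
            c = chroms[int(rng.choice(len(chroms), p=p))]
            start = int(rng.integers(3 * ebr_len, genome.chromosomes[c] - 4 * ebr_len))
            ebrs.append(EBR(unit=c, start=start, end=start + ebr_len, cls="intrachromosomal"))
        report = ebr_flank_contrast(ebrs, genome, alternative="two-sided")
        if report.mannwhitney[1] < alpha:
            rejections += 1
    return {"rate": rejections / n_reps, "n_reps": n_reps, "alpha": alpha}
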
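"""End-to-end orchestration: simulate -> assemble -> anchor -> rearrange ->
cnestats -> report.

Every stage writes its artifacts as plain-text files into the run directory
and a manifest records the seed, parameters and SHA-256 checksums, so
re-running the same configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import yaml

from . import io as kio
from .assembly import (
    AssemblyParams,
    assemble_pcfs,
    attach_coverage,
    build_syntenic_fragments,
    calibrate_threshold,
    find_conflicting_joins,
    pcf_stats,
)
from .cne import ebr_flank_contrast, scan_1kb_windows
from .fish import anchor, anchoring_stats, export_agp, locate_bacs_on_pcfs
from .genome import AssemblyStats, compute_n50, round_half_even
from .homology import build_homology_map, count_interchromosomal_events, detect_ebrs, estimate_map_inversions
from .simulate import SimConfig, pcr_oracle, simulate

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "report_tables"]

STAGES = ("simulate", "assemble", "anchor", "rearrange", "cnestats", "report")


@dataclass
class PipelineConfig:
    """Declarative configuration of a full run."""

    sim: SimConfig = field(default_factory=SimConfig)
    assembly: AssemblyParams = field(default_factory=AssemblyParams)
    stages: Tuple[str, ...] = STAGES
    anchor_policy: str = "split"
    homology_min_segment: int = 150_000
    homology_merge_gap: int = 1_000_000
    ebr_max_len: int = 100_000
    window_size: int = 1000
    excluded_chroms: Tuple[str, ...] = ()
    out_dir: str = "karyoforge_run"
    seed: Optional[int] = None  # overrides sim.seed when set

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.seed is not None:
            self.sim = dataclasses.replace(self.sim, seed=int(self.seed))

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["excluded_chroms"] = list(self.excluded_chroms)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        if "sim" in d and isinstance(d["sim"], dict):
            sim_known = {f.name for f in dataclasses.fields(SimConfig)}
            sim_unknown = set(d["sim"]) - sim_known
            if sim_unknown:
                raise ValueError(f"unknown sim keys: {sorted(sim_unknown)}")
            sim = dict(d["sim"])
            for key in ("macro_length_range", "micro_length_range", "mshsb_length_range"):
                if key in sim and isinstance(sim[key], list):
                    sim[key] = tuple(sim[key])
            d["sim"] = SimConfig(**sim)
        if "assembly" in d and isinstance(d["assembly"], dict):
            d["assembly"] = AssemblyParams(**d["assembly"])
        for key in ("stages", "excluded_chroms"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stats_row(label: str, st: AssemblyStats) -> dict:
    return {
        "set": label,
        "n_units": st.n_units,
        "total_length": st.total_length,
        "n50": st.n50,
        "pct_placed": round_half_even(st.pct_placed),
        "pct_oriented": round_half_even(st.pct_oriented),
    }


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the configured stages; returns the run directory.

    Artifacts: scaffolds/blocks/coverage TSV, PCF TSV and split registry,
    AGP, homology map TSV, EBR BED, window-class table, report tables, and
    ``manifest.json`` with checksums.  Identical configurations produce
    byte-identical artifacts.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stages = set(config.stages)
    written: List[Path] = []
    summary: Dict[str, object] = {}

    sim = None
    if "simulate" in stages:
        logger.info("stage simulate: seed=%d", config.sim.seed)
        sim = simulate(config.sim)
        kio.write_scaffolds(out / "scaffolds.tsv", sim.scaffolds)
        kio.write_blocks(out / "blocks.tsv", sim.blocks)
        kio.write_coverage(out / "coverage.tsv", sim.coverage)
        kio.write_observations(out / "observations.tsv", sim.observations)
        (out / "truth.json").write_text(sim.truth.to_json())
        written += [
            out / "scaffolds.tsv", out / "blocks.tsv", out / "coverage.tsv",
            out / "observations.tsv", out / "truth.json",
        ]
        summary["n_scaffolds"] = len(sim.scaffolds)
        summary["n_derived_chromosomes"] = len(sim.karyotype.chromosomes)
        summary["planted_events"] = sim.truth.event_multiset()

    pcfs = split_registry = None
    calibration = None
    sfs = None
    if "assemble" in stages:
        if sim is None:
            raise RuntimeError("assemble stage requires the simulate stage in this run")
        logger.info("stage assemble")
        sfs = build_syntenic_fragments(sim.blocks, config.assembly)
        joins = attach_coverage(
            find_conflicting_joins(sfs, config.assembly), sim.coverage
        )
        pcr: Dict[Tuple[str, int], str] = {}
        for j in joins:
            if not j.conflict:
                continue
            try:
                pcr[(j.scaffold, j.offset)] = pcr_oracle(
                    (j.scaffold, j.offset), sim.truth,
                    max_span=config.sim.pcr_testable_max_span,
                )
            except KeyError:
                continue
        confirmed = {k for k, v in pcr.items() if v == "confirmed"}
        tested = {k: v for k, v in pcr.items() if v in ("confirmed", "refuted")}
        if tested:
            calibration = calibrate_threshold(joins, pcr)
            threshold = calibration.threshold
        else:
            threshold = config.assembly.min_intracov_threshold
        pcfs, split_registry = assemble_pcfs(
            sim.scaffolds, sfs, sim.coverage, config.assembly,
            confirmed=confirmed, threshold=threshold,
        )
        kio.write_pcfs(out / "pcfs.tsv", pcfs)
        with open(out / "splits.tsv", "w") as fh:
            fh.write("scaffold\toffset\tcoverage\treason\n")
            for s in split_registry:
                fh.write(f"{s['scaffold']}\t{s['offset']}\t{s['coverage']}\t{s['reason']}\n")
        written += [out / "pcfs.tsv", out / "splits.tsv"]
        summary["pcr"] = {
            "tested": len(tested),
            "confirmed": sum(1 for v in tested.values() if v == "confirmed"),
            "refuted": sum(1 for v in tested.values() if v == "refuted"),
            "untestable": sum(1 for v in pcr.values() if v == "untestable"),
            "threshold": threshold,
            "agreement": calibration.agreement if calibration else None,
        }
        summary["n_pcfs"] = len(pcfs)
        summary["n_splits"] = len(split_registry)

    assemblies = None
    if "anchor" in stages:
        if pcfs is None or sim is None:
            raise RuntimeError("anchor stage requires the assemble stage in this run")
        logger.info("stage anchor")
        locations, unmapped = locate_bacs_on_pcfs(sim.bacs, sfs, pcfs)
        observations = [ob for ob in sim.observations if ob[0] in locations or ob[0] in unmapped]
        assemblies, disagreements = anchor(
            pcfs, locations, observations,
            policy=config.anchor_policy, unmapped=unmapped,
        )
        (out / "assembly.agp").write_text("\n".join(export_agp(assemblies)) + "\n")
        (out / "disagreements.json").write_text(json.dumps(disagreements, indent=0))
        written += [out / "assembly.agp", out / "disagreements.json"]
        summary["n_chromosomes_assembled"] = len(assemblies)
        summary["n_disagreements"] = len(disagreements)

    hmap = None
    ebrs = None
    counts = None
    if "rearrange" in stages:
        if assemblies is None:
            raise RuntimeError("rearrange stage requires the anchor stage in this run")
        logger.info("stage rearrange")
        chains = {c: a.member_chain() for c, a in assemblies.items()}
        hmap = build_homology_map(
            chains, sfs,
            min_segment=config.homology_min_segment,
            merge_gap=config.homology_merge_gap,
        )
        counts = count_interchromosomal_events(hmap)
        counts.inversions_estimate = int(estimate_map_inversions(hmap))
        ebrs = detect_ebrs(hmap, max_len=config.ebr_max_len,
                           ref_lengths=sim.ancestor.chromosomes)
        kio.write_homology_map(out / "homology_map.tsv", hmap)
        kio.write_ebrs_bed(out / "ebrs.bed", ebrs)
        written += [out / "homology_map.tsv", out / "ebrs.bed"]
        summary["events"] = {
            "fusions": counts.fusions,
            "fissions": counts.fissions,
            "inversions_estimate": counts.inversions_estimate,
            "intact_units": sorted(counts.intact_units),
            "identity_holds": counts.identity_holds(),
        }

    scan = None
    if "cnestats" in stages:
        if ebrs is None or sim is None:
            raise RuntimeError("cnestats stage requires the rearrange stage in this run")
        logger.info("stage cnestats")
        scan = scan_1kb_windows(
            sim.ancestor, ebrs,
            window=config.window_size,
            excluded_chroms=config.excluded_chroms,
        )
        scan.table.to_csv(out / "windows.tsv", sep="\t", index=False)
        written.append(out / "windows.tsv")
        contrast = None
        usable_ebrs = [e for e in ebrs if not e.excluded_from_cne]
        if len(usable_ebrs) >= 2:
            contrast = ebr_flank_contrast(usable_ebrs, sim.ancestor)
        tests = {
            "class_mean_bases": scan.class_mean_bases,
            "class_mean_density": scan.class_mean_density,
            "genome_mean_bases": scan.genome_mean_bases,
            "genome_mean_density": scan.genome_mean_density,
            "flank_contrast": None
            if contrast is None
            else {
                "n_ebrs": contrast.n_ebrs,
                "group_means": contrast.group_means,
                "kruskal": list(contrast.kruskal),
                "mannwhitney": list(contrast.mannwhitney),
                "notes": contrast.notes,
            },
        }
        (out / "cne_tests.json").write_text(json.dumps(tests, indent=0, sort_keys=True))
        written.append(out / "cne_tests.json")

    if "report" in stages:
        logger.info("stage report")
        for p in report_tables(out, sim=sim, pcfs=pcfs, assemblies=assemblies, scan=scan, summary=summary):
            written.append(p)

    manifest = {
        "seed": config.sim.seed,
        "config": config.to_dict(),
        "stages": sorted(stages),
        "summary": summary,
        "artifacts": {p.name: _sha256(p) for p in sorted(set(written))},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    logger.info("pipeline finished in %.1f s", time.time() - t0)
    return out


def report_tables(run_dir: Path, sim=None, pcfs=None, assemblies=None, scan=None, summary=None) -> List[Path]:
    """Emit the split-statistics, assembly-statistics and CNE-density class
    tables as TSV; missing stage outputs leave explicit gaps."""
    run_dir = Path(run_dir)
    written: List[Path] = []
    summary = summary or {}

    # split-region statistics
    split_path = run_dir / "report_split_stats.tsv"
    with open(split_path, "w") as fh:
        fh.write("statistic\tvalue\n")
        pcr = summary.get("pcr")
        if pcr is None:
            fh.write("pcr_testing\tNA\n")
        else:
            for k in ("tested", "confirmed", "refuted", "untestable", "threshold", "agreement"):
                fh.write(f"{k}\t{pcr.get(k)}\n")
    written.append(split_path)

    # assembly statistics
    stats_path = run_dir / "report_assembly_stats.tsv"
    rows = []
    if sim is not None:
        lengths = [s.length for s in sim.scaffolds]
        rows.append(
            _stats_row(
                "original_scaffolds",
                AssemblyStats(len(lengths), sum(lengths), compute_n50(lengths)),
            )
        )
        if pcfs:
            rows.append(_stats_row("pcfs", pcf_stats(pcfs, sim.scaffolds)))
        if assemblies:
            rows.append(
                _stats_row("anchored_chromosomes", anchoring_stats(assemblies, sim.scaffolds))
            )
    with open(stats_path, "w") as fh:
        cols = ["set", "n_units", "total_length", "n50", "pct_placed", "pct_oriented"]
        fh.write("\t".join(cols) + "\n")
        if rows:
            for r in rows:
                fh.write("\t".join(str(r[c]) for c in cols) + "\n")
        else:
            fh.write("NA\tNA\tNA\tNA\tNA\tNA\n")
    written.append(stats_path)

    # CNE density class table
    cne_path = run_dir / "report_cne_density.tsv"
    with open(cne_path, "w") as fh:
        fh.write("class\tmean_cne_bases\tmean_density\n")
        if scan is None:
            for cls in ("Genome", "msHSB", "Intra", "Fusion", "Fission"):
                fh.write(f"{cls}\tNA\tNA\n")
        else:
            fh.write(
                f"Genome\t{scan.genome_mean_bases:.2f}\t{scan.genome_mean_density:.3f}\n"
            )
            label = {
                "msHSB": "msHSB", "intrachromosomal": "Intra",
                "fusion": "Fusion", "fission": "Fission",
            }
            for cls in ("msHSB", "intrachromosomal", "fusion", "fission"):
                mb = scan.class_mean_bases.get(cls, float("nan"))
                md = scan.class_mean_density.get(cls, float("nan"))
                if mb != mb:  # NaN
                    fh.write(f"{label[cls]}\tNA\tNA\n")
                else:
                    fh.write(f"{label[cls]}\t{mb:.2f}\t{md:.3f}\n")
    written.append(cne_path)
    return written
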
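"""Readers and writers for the package's plain-text exchange formats.

All tabular formats are tab-separated with a single header line (homology
maps additionally allow leading ``#`` comment lines); genomic coordinates
are 0-based half-open except in AGP output.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .assembly import PCF, PcfMember
from .homology import EBR, HomologyMap, HomologySegment, UnitSet
from .simulate import AlignmentBlock, Scaffold

__all__ = [
    "write_blocks", "read_blocks",
    "write_scaffolds", "read_scaffolds",
    "write_coverage", "read_coverage",
    "write_pcfs", "read_pcfs",
    "write_homology_map", "read_homology_map",
    "write_ebrs_bed", "read_ebrs_bed",
    "write_observations", "read_observations",
]

BLOCK_COLUMNS = ["ref_chrom", "ref_start", "ref_end", "tgt_scaffold", "tgt_start", "tgt_end", "strand"]


def write_blocks(path, blocks: Sequence[AlignmentBlock]) -> None:
    df = pd.DataFrame(
        [
            (b.ref_chrom, b.ref_start, b.ref_end, b.scaffold, b.tgt_start, b.tgt_end, b.strand)
            for b in blocks
        ],
        columns=BLOCK_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_blocks(path) -> List[AlignmentBlock]:
    df = pd.read_csv(path, sep="\t")
    return [
        AlignmentBlock(
            str(r.ref_chrom), int(r.ref_start), int(r.ref_end),
            str(r.tgt_scaffold), int(r.tgt_start), int(r.tgt_end), str(r.strand),
        )
        for r in df.itertuples()
    ]


def write_scaffolds(path, scaffolds: Sequence[Scaffold]) -> None:
    pd.DataFrame(
        [(s.id, s.length) for s in scaffolds], columns=["scaffold_id", "length"]
    ).to_csv(path, sep="\t", index=False)


def read_scaffolds(path) -> List[Scaffold]:
    df = pd.read_csv(path, sep="\t")
    return [Scaffold(str(r.scaffold_id), int(r.length)) for r in df.itertuples()]


def write_coverage(path, coverage: Sequence[Tuple[str, int, int]]) -> None:
    pd.DataFrame(
        coverage, columns=["scaffold_id", "junction_offset", "spanning_pairs"]
    ).to_csv(path, sep="\t", index=False)


def read_coverage(path) -> List[Tuple[str, int, int]]:
    df = pd.read_csv(path, sep="\t")
    return [
        (str(r.scaffold_id), int(r.junction_offset), int(r.spanning_pairs))
        for r in df.itertuples()
    ]


def write_pcfs(path, pcfs: Sequence[PCF]) -> None:
    rows = []
    for p in pcfs:
        for rank, m in enumerate(p.members):
            rows.append((p.id, rank, m.scaffold, m.start, m.end, m.strand))
    pd.DataFrame(
        rows,
        columns=["pcf_id", "rank", "scaffold_id", "scaffold_start", "scaffold_end", "strand"],
    ).to_csv(path, sep="\t", index=False)


def read_pcfs(path) -> List[PCF]:
    df = pd.read_csv(path, sep="\t")
    pcfs: Dict[str, List[Tuple[int, PcfMember]]] = {}
    for r in df.itertuples():
        pcfs.setdefault(str(r.pcf_id), []).append(
            (
                int(r.rank),
                PcfMember(str(r.scaffold_id), int(r.scaffold_start), int(r.scaffold_end), str(r.strand)),
            )
        )
    return [
        PCF(pid, [m for _rank, m in sorted(members)])
        for pid, members in pcfs.items()
    ]


def write_homology_map(path, hmap: HomologyMap) -> None:
    with open(path, "w") as fh:
        fh.write("tgt_chrom\ttgt_start\ttgt_end\tref_unit\tref_start\tref_end\tstrand\tnote\n")
        for chrom, segs in hmap.segments.items():
            for s in segs:
                fh.write(
                    "\t".join(
                        [
                            chrom,
                            _na(s.tgt_start), _na(s.tgt_end),
                            s.unit,
                            _na(s.ref_start), _na(s.ref_end),
                            s.strand,
                            s.note,
                        ]
                    )
                    + "\n"
                )


def _na(x: Optional[int]) -> str:
    return "NA" if x is None else str(x)


def _un_na(x: str) -> Optional[int]:
    return None if x in ("NA", "", "nan") else int(x)


def read_homology_map(
    path, unit_set: Optional[UnitSet] = None, species: str = ""
) -> HomologyMap:
    segments: Dict[str, List[HomologySegment]] = {}
    with open(path) as fh:
        header: Optional[List[str]] = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if header is None:
                header = parts
                continue
            row = dict(zip(header, parts))
            seg = HomologySegment(
                tgt_chrom=row["tgt_chrom"],
                unit=row["ref_unit"],
                strand=row.get("strand", "+"),
                tgt_start=_un_na(row.get("tgt_start", "NA")),
                tgt_end=_un_na(row.get("tgt_end", "NA")),
                ref_start=_un_na(row.get("ref_start", "NA")),
                ref_end=_un_na(row.get("ref_end", "NA")),
                note=row.get("note", ""),
            )
            segments.setdefault(seg.tgt_chrom, []).append(seg)
    return HomologyMap(segments=segments, unit_set=unit_set, species=species)


def write_ebrs_bed(path, ebrs: Sequence[EBR]) -> None:
    """BED with the class in the name field (class[,excluded])."""
    with open(path, "w") as fh:
        for e in ebrs:
            name = e.cls + (",excluded" if e.excluded_from_cne else "")
            fh.write(f"{e.unit}\t{e.start}\t{e.end}\t{name}\n")


def read_ebrs_bed(path) -> List[EBR]:
    out: List[EBR] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, name = line.split("\t")[:4]
            cls, _, flag = name.partition(",")
            out.append(
                EBR(
                    unit=chrom, start=int(start), end=int(end), cls=cls,
                    excluded_from_cne=flag == "excluded",
                )
            )
    return out


def write_observations(path, observations: Sequence[Tuple[str, str, int]]) -> None:
    pd.DataFrame(
        list(observations), columns=["bac_id", "chrom", "order_index"]
    ).to_csv(path, sep="\t", index=False)


def read_observations(path) -> List[Tuple[str, str, int]]:
    df = pd.read_csv(path, sep="\t")
    return [(str(r.bac_id), str(r.chrom), int(r.order_index)) for r in df.itertuples()]
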
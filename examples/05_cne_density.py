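"""CNE density contrasts around evolutionary breakpoint regions.

Detects EBRs from the exact homology map of a biased simulation, scans
1-kb windows genome-wide, and tests the EBR-vs-flank depletion.
"""

from karyoforge import detect_ebrs, scan_1kb_windows
from karyoforge.cne import ebr_flank_contrast
from karyoforge.experiments import (
    DEPLETION_SIM, snap_to_windows, truth_homology_map,
)
from karyoforge.simulate import apply_rearrangements, generate_ancestor
import dataclasses
import numpy as np

sim = dataclasses.replace(DEPLETION_SIM, seed=0)
ss = np.random.SeedSequence(sim.seed)
r_anc, r_evt = [np.random.default_rng(s) for s in ss.spawn(2)]
genome = generate_ancestor(sim, r_anc)
kary, _ = apply_rearrangements(genome, sim, r_evt)

hmap = truth_homology_map(kary, sim.telomere_unaligned)
ebrs = snap_to_windows(detect_ebrs(hmap, ref_lengths=genome.chromosomes), genome)
print(f"{len(ebrs)} EBRs detected "
      f"({sum(e.cls == 'intrachromosomal' for e in ebrs)} intra, "
      f"{sum(e.cls == 'fusion' for e in ebrs)} fusion, "
      f"{sum(e.cls == 'fission' for e in ebrs)} fission)")

scan = scan_1kb_windows(genome, ebrs)
print(f"genome-wide mean CNE density {scan.genome_mean_density:.3f}")
for cls in ("msHSB", "intrachromosomal", "fusion", "fission"):
    print(f"  {cls:18s} {scan.class_mean_density[cls]:.3f}")

rep = ebr_flank_contrast(ebrs, genome, alternative="less")
print(f"flank contrast over {rep.n_ebrs} EBRs: "
      f"EBR mean {rep.group_means['EBR']:.3f}, "
      f"one-sided Mann-Whitney p = {rep.mannwhitney[1]:.2e}")
# The class ordering msHSB > genome > intra > fusion > fission and the
# depleted EBR mean reproduce the qualitative pattern seen in real avian
# genome comparisons.
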
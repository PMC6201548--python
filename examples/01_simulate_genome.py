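"""Simulate an avian-like genome with planted rearrangements.

Generates a small multichromosomal ancestor carrying CNE and msHSB tracks,
applies fissions, fusions and inversions with a CNE-poor breakpoint bias,
and fragments the result into scaffolds with observable evidence.
"""

from karyoforge import SimConfig, simulate

cfg = SimConfig(seed=1)
res = simulate(cfg)

g = res.ancestor
print(f"ancestor: {len(g.chromosomes)} chromosomes, {g.total_length/1e6:.1f} Mb")
print(f"CNE density {g.track_density('CNE'):.3f} (target {cfg.cne_target_density})")
print(f"msHSB track: {g.track_total('msHSB')/1e6:.1f} Mb")
print(f"planted events: {res.truth.event_multiset()}")
print(f"derived karyotype: {len(res.karyotype.chromosomes)} chromosomes")
print(f"scaffolds: {len(res.scaffolds)}, alignment blocks: {len(res.blocks)}")
chim = sum(j["chimeric"] for j in res.truth.joins)
print(f"intra-scaffold junctions: {len(res.truth.joins)} ({chim} chimeric)")
# The event counts are what a perfect downstream analysis should recover;
# the chimeric junction count is what coverage + PCR evidence must catch.
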
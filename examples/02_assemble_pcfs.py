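"""Reference-assisted assembly: syntenic fragments, PCR-calibrated chimera
splitting, and PCF construction.

Builds SFs from alignment blocks, flags conflicting scaffold joins,
calibrates the spanning-coverage split threshold against the in-silico PCR
oracle, and chains scaffold fragments into predicted chromosome fragments.
"""

from karyoforge import (
    AssemblyParams, SimConfig, assemble_pcfs, build_syntenic_fragments,
    calibrate_threshold, find_conflicting_joins, pcf_stats, pcr_oracle, simulate,
)
from karyoforge.assembly import attach_coverage

res = simulate(SimConfig(seed=1))
params = AssemblyParams()

sfs = build_syntenic_fragments(res.blocks, params)
joins = attach_coverage(find_conflicting_joins(sfs, params), res.coverage)
conflicts = [j for j in joins if j.conflict]
print(f"{len(sfs)} syntenic fragments, {len(conflicts)} conflicting joins")

pcr = {}
for j in conflicts:
    try:
        pcr[(j.scaffold, j.offset)] = pcr_oracle((j.scaffold, j.offset), res.truth)
    except KeyError:
        pass
tested = {k: v for k, v in pcr.items() if v != "untestable"}
print(f"PCR: {len(tested)} testable joins "
      f"({sum(v == 'confirmed' for v in tested.values())} confirmed)")

cal = calibrate_threshold(joins, pcr)
print(f"calibrated spanning-pair threshold: {cal.threshold} "
      f"(agreement {cal.agreement}/{cal.tested})")

confirmed = {k for k, v in pcr.items() if v == "confirmed"}
pcfs, splits = assemble_pcfs(
    res.scaffolds, sfs, res.coverage, params,
    confirmed=confirmed, threshold=cal.threshold,
)
st = pcf_stats(pcfs, res.scaffolds)
print(f"{len(pcfs)} PCFs, {len(splits)} scaffolds split; "
      f"N50 {st.n50/1e6:.2f} Mb, {st.pct_placed:.2f}% of input assembly")
# A threshold between the chimeric (~5x) and true (~400x) coverage regimes
# splits planted chimeras while keeping genuine rearrangement junctions.
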
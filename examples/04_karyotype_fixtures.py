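"""Interchromosomal rearrangement counts for three avian karyotypes.

Loads the packaged chromosome-level homology maps (ostrich, budgerigar,
saker falcon vs chicken/ancestral units) and counts fusions, fissions and
intact homologs under the junction/piece conventions.
"""

from karyoforge import count_interchromosomal_events, load_fixture

for species in ("ostrich", "budgerigar", "saker"):
    fx = load_fixture(species)
    c = count_interchromosomal_events(fx.map)
    print(f"{species} ({fx.unit_set.name} units): "
          f"{c.n_target_chromosomes} chromosomes, "
          f"{c.fusions} fusions, {c.fissions} fissions, "
          f"{len(c.intact_units)} intact homologs")
    if fx.unit_set.micro_units:
        print(f"  microchromosomes: {len(c.fused_micro_units)} fused, "
              f"{len(c.intact_micro_units)} intact")
    assert c.identity_holds()
# The identity #chromosomes = #units + fissions - fusions holds for every
# map; the ostrich differs from chicken by a single event (the GGA4 q/p
# arrangement), while the saker shows 12 fusions and 5 fissions.
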
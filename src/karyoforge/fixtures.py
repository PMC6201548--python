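"""Packaged karyotype homology-map fixtures for three avian species.

The maps encode the chromosome-level homology of the ostrich, budgerigar
and saker falcon karyotypes against chicken/ancestral avian units, as
established by comparative FISH mapping of chromosome-level assemblies.
They are order-only maps (no reference coordinates) and drive the
interchromosomal event counts:

* ostrich: every tested chicken homolog conserved except GGA4 (q-arm plus a
  separate ancestral p-arm microchromosome) — a single interchromosomal
  difference;
* saker falcon (chicken units): 12 fusions, 5 fissions, 8 intact homologs;
* budgerigar (ancestral units, chicken 4p separate): 9 fusion junctions,
  3 fissions, 13 intact homologs; of the 18 mapped microchromosome units 7
  are fused and 11 remain intact.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from .homology import HomologyMap, UnitSet, ancestral_units, chicken_units
from .io import read_homology_map

__all__ = ["FixtureMap", "load_fixture", "FIXTURE_SPECIES"]

FIXTURE_SPECIES = ("ostrich", "budgerigar", "saker")

_UNIT_SETS = {
    "ostrich": chicken_units,
    "saker": chicken_units,
    "budgerigar": ancestral_units,
}


@dataclass
class FixtureMap:
    species: str
    map: HomologyMap
    unit_set: UnitSet


def load_fixture(species: str) -> FixtureMap:
    """Load a packaged species homology map with its declared unit set."""
    if species not in FIXTURE_SPECIES:
        raise KeyError(
            f"unknown species {species!r}; choose from {FIXTURE_SPECIES}"
        )
    unit_set = _UNIT_SETS[species]()
    ref = resources.files("karyoforge.data").joinpath(f"fixtures/{species}.tsv")
    with resources.as_file(ref) as path:
        hmap = read_homology_map(path, unit_set=unit_set, species=species)
    return FixtureMap(species=species, map=hmap, unit_set=unit_set)
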
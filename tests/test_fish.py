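import pytest

from karyoforge import anchor, anchoring_stats, export_agp, locate_bacs_on_pcfs, parse_agp
from karyoforge.assembly import PCF, PcfMember, SyntenicFragment
from karyoforge.fish import ChromosomeAssembly, PlacedUnit
from karyoforge.intervals import SeqInterval
from karyoforge.simulate import BacMarker, Scaffold


def make_sf(scaf, ts, te, ref, rs, re, strand="+"):
    return SyntenicFragment(scaf, ts, te, ref, rs, re, strand)


@pytest.fixture
def simple_layout():
    """One PCF of two members on reference chromosome r1."""
    sf1 = make_sf("sA", 0, 1_000_000, "r1", 0, 1_000_000)
    sf2 = make_sf("sB", 0, 1_000_000, "r1", 1_000_000, 2_000_000)
    pcf = PCF(
        "PCF_r1",
        [
            PcfMember("sA", 0, 1_000_000, "+", [sf1]),
            PcfMember("sB", 0, 1_000_000, "+", [sf2]),
        ],
    )
    bacs = [
        BacMarker("b1", SeqInterval("r1", 100_000, 100_001)),
        BacMarker("b2", SeqInterval("r1", 800_000, 800_001)),
        BacMarker("b3", SeqInterval("r1", 1_200_000, 1_200_001)),
        BacMarker("b4", SeqInterval("r1", 1_900_000, 1_900_001)),
        BacMarker("gap", SeqInterval("r2", 5_000, 5_001)),
    ]
    return pcf, [sf1, sf2], bacs


class TestLocateBacs:
    def test_offsets_strand_aware(self, simple_layout):
        pcf, sfs, bacs = simple_layout
        loc, unmapped = locate_bacs_on_pcfs(bacs, sfs, [pcf])
        assert unmapped == ["gap"]
        assert loc["b1"].offset == 100_000
        assert loc["b3"].offset == 1_200_000
        # reverse the second member: offsets count from the other end
        pcf.members[1] = PcfMember("sB", 0, 1_000_000, "-", [sfs[1]])
        loc2, _ = locate_bacs_on_pcfs(bacs, sfs, [pcf])
        assert loc2["b3"].offset == 1_000_000 + (1_000_000 - 1 - 200_000)

    def test_monotone_for_identity(self, simple_layout):
        pcf, sfs, bacs = simple_layout
        loc, _ = locate_bacs_on_pcfs(bacs, sfs, [pcf])
        offsets = [loc[b].offset for b in ("b1", "b2", "b3", "b4")]
        assert offsets == sorted(offsets)


class TestAnchor:
    def obs(self, *tuples):
        return [t for t in tuples]

    def test_ascending_orders_place_plus(self, simple_layout):
        pcf, sfs, bacs = simple_layout
        loc, unmapped = locate_bacs_on_pcfs(bacs, sfs, [pcf])
        asm, dis = anchor(
            [pcf], loc, self.obs(("b1", "chrA", 0), ("b4", "chrA", 1)), unmapped=unmapped
        )
        assert dis == []
        unit = asm["chrA"].units[0]
        assert unit.strand == "+"

    def test_reversed_observation_places_minus(self, simple_layout):
        pcf, sfs, bacs = simple_layout
        loc, unmapped = locate_bacs_on_pcfs(bacs, sfs, [pcf])
        asm, _ = anchor(
            [pcf], loc, self.obs(("b1", "chrA", 1), ("b4", "chrA", 0)), unmapped=unmapped
        )
        assert asm["chrA"].units[0].strand == "-"

    def test_single_offset_is_unoriented(self, simple_layout):
        pcf, sfs, bacs = simple_layout
        loc, unmapped = locate_bacs_on_pcfs(bacs, sfs, [pcf])
        asm, _ = anchor([pcf], loc, self.obs(("b1", "chrA", 0)), unmapped=unmapped)
        assert asm["chrA"].units[0].strand == "?"

    def test_two_chromosomes_is_disagreement(self, simple_layout):
        pcf, sfs, bacs = simple_layout
        loc, unmapped = locate_bacs_on_pcfs(bacs, sfs, [pcf])
        asm, dis = anchor(
            [pcf], loc,
            self.obs(("b1", "chrA", 0), ("b2", "chrA", 1), ("b3", "chrB", 0), ("b4", "chrB", 1)),
            unmapped=unmapped,
        )
        assert len(dis) == 1 and dis[0]["reason"] == "multiple chromosomes"
        assert asm == {}  # report policy leaves it unplaced

    def test_split_policy_places_members_separately(self, simple_layout):
        pcf, sfs, bacs = simple_layout
        loc, unmapped = locate_bacs_on_pcfs(bacs, sfs, [pcf])
        asm, dis = anchor(
            [pcf], loc,
            self.obs(("b1", "chrA", 0), ("b2", "chrA", 1), ("b3", "chrB", 0), ("b4", "chrB", 1)),
            policy="split", unmapped=unmapped,
        )
        assert set(asm) == {"chrA", "chrB"}
        assert asm["chrA"].units[0].members[0].scaffold == "sA"
        assert asm["chrB"].units[0].members[0].scaffold == "sB"

    def test_unknown_bac_errors(self, simple_layout):
        pcf, sfs, bacs = simple_layout
        loc, unmapped = locate_bacs_on_pcfs(bacs, sfs, [pcf])
        with pytest.raises(KeyError):
            anchor([pcf], loc, self.obs(("nope", "chrA", 0)), unmapped=unmapped)


class TestAnchoringStats:
    def test_arithmetic(self):
        asm = {
            "c1": ChromosomeAssembly(
                "c1",
                [
                    PlacedUnit("u1", "+", [PcfMember("s1", 0, 6, "+")]),
                    PlacedUnit("u2", "?", [PcfMember("s2", 0, 4, "+")]),
                ],
            )
        }
        st = anchoring_stats(asm, [Scaffold("s1", 6), Scaffold("s2", 4)])
        assert st.pct_placed == pytest.approx(100.0)
        assert st.pct_oriented == pytest.approx(60.0)

    def test_oriented_never_exceeds_placed(self, small_clean_result):
        from karyoforge.assembly import AssemblyParams, assemble_pcfs, build_syntenic_fragments

        res = small_clean_result
        sfs = build_syntenic_fragments(res.blocks, AssemblyParams())
        pcfs, _ = assemble_pcfs(res.scaffolds, sfs, res.coverage, AssemblyParams(), threshold=0)
        loc, unmapped = locate_bacs_on_pcfs(res.bacs, sfs, pcfs)
        obs = [o for o in res.observations if o[0] in loc or o[0] in unmapped]
        asm, _ = anchor(pcfs, loc, obs, policy="split", unmapped=unmapped)
        st = anchoring_stats(asm, res.scaffolds)
        assert st.pct_oriented <= st.pct_placed <= 100.0


class TestAgp:
    def _assembly(self):
        return {
            "c1": ChromosomeAssembly(
                "c1",
                [
                    PlacedUnit(
                        "u1", "+",
                        [PcfMember("s1", 0, 5_000, "+"), PcfMember("s2", 100, 3_100, "-")],
                    )
                ],
            )
        }

    def test_single_component_row(self):
        asm = {
            "c1": ChromosomeAssembly(
                "c1", [PlacedUnit("u1", "+", [PcfMember("s1", 0, 5_000, "+")])]
            )
        }
        lines = export_agp(asm)
        assert lines[1].split("\t") == ["c1", "1", "5000", "1", "W", "s1", "1", "5000", "+"]

    def test_gap_rows_and_contiguity(self):
        lines = export_agp(self._assembly())
        rows = [l.split("\t") for l in lines if not l.startswith("#")]
        assert len(rows) == 3 and rows[1][4] == "U" and rows[1][5] == "100"
        # object coordinates are contiguous
        assert int(rows[1][1]) == int(rows[0][2]) + 1
        assert int(rows[2][1]) == int(rows[1][2]) + 1

    def test_round_trip(self):
        asm = self._assembly()
        chains = parse_agp(export_agp(asm))
        assert chains["c1"] == asm["c1"].member_chain()

    def test_overlapping_components_rejected(self):
        lines = [
            "c1\t1\t100\t1\tW\ts1\t1\t100\t+",
            "c1\t101\t200\t2\tW\ts1\t50\t149\t+",
        ]
        with pytest.raises(ValueError):
            parse_agp(lines)

    def test_non_contiguous_object_rejected(self):
        lines = [
            "c1\t1\t100\t1\tW\ts1\t1\t100\t+",
            "c1\t150\t250\t2\tW\ts2\t1\t101\t+",
        ]
        with pytest.raises(ValueError):
            parse_agp(lines)
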
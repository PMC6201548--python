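import dataclasses

import numpy as np
import pytest
from scipy import stats as sps

from karyoforge import (
    Genome,
    SimConfig,
    apply_rearrangements,
    emit_bac_panel,
    fragment_and_observe,
    generate_ancestor,
    pcr_oracle,
    sample_breakpoint,
    simulate,
)
from karyoforge.cne import mann_whitney_u
from karyoforge.genome import cne_fraction
from karyoforge.intervals import SeqInterval
from tests.conftest import SMALL_SIM


def one_chrom_config(**kw):
    base = dict(
        n_macro=1, n_micro=0, macro_length_range=(10_000_000, 10_000_001),
        mshsb_count=2, n_inversions=0, n_fusions=0, n_fissions=0, seed=0,
    )
    base.update(kw)
    return SimConfig(**base)


class TestGenerateAncestor:
    def test_zero_density_gives_empty_track(self):
        g = generate_ancestor(one_chrom_config(cne_target_density=0.0))
        assert g.track_total("CNE") == 0

    def test_realized_density_near_target(self):
        g = generate_ancestor(one_chrom_config())
        assert 0.082 <= g.track_density("CNE") <= 0.092

    def test_mshsb_enrichment(self):
        g = generate_ancestor(one_chrom_config(seed=3))
        hsb = g.track("msHSB", "anc1")
        hsb_bases = sum(
            cne_fraction(SeqInterval("anc1", int(s), int(e)), g.track("CNE", "anc1")) * (e - s)
            for s, e in hsb
        )
        hsb_density = hsb_bases / max(sum(e - s for s, e in hsb), 1)
        assert hsb_density > g.track_density("CNE")

    def test_determinism(self):
        g1 = generate_ancestor(SMALL_SIM)
        g2 = generate_ancestor(SMALL_SIM)
        assert g1.chromosomes == g2.chromosomes
        for c in g1.chromosomes:
            assert np.array_equal(g1.track("CNE", c), g2.track("CNE", c))

    def test_infeasible_density_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(cne_target_density=1.5)


class TestSampleBreakpoint:
    def test_gamma_zero_is_uniform_over_windows(self):
        g = Genome({"c": 50_000})
        g.set_track("CNE", {"c": [(0, 500), (10_000, 12_000)]})
        g.set_track("msHSB", {})
        rng = np.random.default_rng(0)
        counts = np.zeros(50)
        for _ in range(10_000):
            _, pos = sample_breakpoint(g, 0.0, rng)
            counts[pos // 1000] += 1
        p = sps.chisquare(counts).pvalue
        assert p > 0.01

    def test_all_mass_on_zero_density_window(self):
        g = Genome({"c": 2_000})
        g.set_track("CNE", {"c": [(0, 1_000)]})
        rng = np.random.default_rng(0)
        for _ in range(50):
            _, pos = sample_breakpoint(g, 1.0, rng)
            assert pos >= 1_000

    def test_higher_gamma_means_lower_density(self):
        g = generate_ancestor(one_chrom_config(seed=5))
        track = g.track("CNE", "anc1")

        def mean_density(gamma, seed):
            rng = np.random.default_rng(seed)
            vals = []
            for _ in range(2_000):
                chrom, pos = sample_breakpoint(g, gamma, rng)
                w = (pos // 1000) * 1000
                vals.append(cne_fraction(SeqInterval(chrom, w, w + 1000), track))
            return float(np.mean(vals))

        assert mean_density(8.0, 1) < mean_density(1.0, 1)

    def test_all_zero_weight_errors(self):
        g = Genome({"c": 1_000})
        g.set_track("CNE", {"c": [(0, 1_000)]})
        with pytest.raises(ValueError):
            sample_breakpoint(g, 1.0, np.random.default_rng(0))


class TestApplyRearrangements:
    def test_zero_events_is_identity(self):
        g = generate_ancestor(SMALL_SIM)
        cfg = dataclasses.replace(SMALL_SIM, n_inversions=0, n_fusions=0, n_fissions=0)
        kary, truth = apply_rearrangements(g, cfg)
        assert len(truth.events) == 0
        assert {c: segs for c, segs in kary.chromosomes.items()} == {
            c: [(c, 0, L, 1)] for c, L in g.chromosomes.items()
        }

    def test_single_fusion_conserves_length(self):
        g = generate_ancestor(SMALL_SIM)
        cfg = dataclasses.replace(SMALL_SIM, n_inversions=0, n_fusions=1, n_fissions=0)
        kary, truth = apply_rearrangements(g, cfg)
        assert len(kary.chromosomes) == len(g.chromosomes) - 1
        assert kary.total_length == g.total_length

    def test_inversion_conserves_everything(self):
        g = generate_ancestor(SMALL_SIM)
        cfg = dataclasses.replace(SMALL_SIM, n_inversions=1, n_fusions=0, n_fissions=0)
        kary, truth = apply_rearrangements(g, cfg)
        assert len(kary.chromosomes) == len(g.chromosomes)
        # per-chromosome lengths unchanged and CNE bases conserved
        for c, L in g.chromosomes.items():
            assert kary.chrom_length(c) == L
        total_cne = sum(
            kary.cne_bases_in(c, 0, kary.chrom_length(c)) for c in kary.chromosomes
        )
        assert total_cne == g.track_total("CNE")

    def test_full_event_mix_conserves_totals(self, small_sim_result):
        res = small_sim_result
        assert res.karyotype.total_length == res.ancestor.total_length
        total_cne = sum(
            res.karyotype.cne_bases_in(c, 0, res.karyotype.chrom_length(c))
            for c in res.karyotype.chromosomes
        )
        assert total_cne == res.ancestor.track_total("CNE")

    def test_infeasible_counts_rejected(self):
        g = generate_ancestor(SMALL_SIM)
        cfg = dataclasses.replace(SMALL_SIM, n_fusions=30, n_fissions=0, n_inversions=0)
        with pytest.raises(ValueError):
            apply_rearrangements(g, cfg)

    def test_planted_breakpoints_are_cne_depleted(self):
        """Mean CNE density at planted breakpoints is below genome-wide
        (one-sided Mann-Whitney, about 100 events)."""
        cfg = SimConfig(n_inversions=40, n_fusions=10, n_fissions=10, seed=2)
        g = generate_ancestor(cfg)
        kary, truth = apply_rearrangements(g, cfg, np.random.default_rng(2))
        planted = []
        for iv in truth.planted_breakpoint_windows()[:100]:
            planted.append(cne_fraction(iv, g.track("CNE", iv.chrom)))
        rng = np.random.default_rng(3)
        background = []
        chroms = list(g.chromosomes)
        for _ in range(1000):
            c = chroms[int(rng.integers(len(chroms)))]
            w = int(rng.integers(0, g.chromosomes[c] // 1000 - 1)) * 1000
            background.append(cne_fraction(SeqInterval(c, w, w + 1000), g.track("CNE", c)))
        assert np.mean(planted) < np.mean(background)
        _, p = mann_whitney_u(planted, background, alternative="less")
        assert p < 0.01


class TestFragmentAndObserve:
    def test_no_chimeras_when_rate_zero(self, small_clean_result):
        assert all(not j["chimeric"] for j in small_clean_result.truth.joins)

    def test_chimeric_joins_registered(self, small_sim_result):
        assert any(j["chimeric"] for j in small_sim_result.truth.joins)

    def test_blocks_tile_scaffolds_within_margins(self, small_sim_result):
        res = small_sim_result
        by_scaffold = {}
        for b in res.blocks:
            by_scaffold.setdefault(b.scaffold, []).append(b)
        lengths = {s.id: s.length for s in res.scaffolds}
        for sid, bl in by_scaffold.items():
            bl.sort(key=lambda b: b.tgt_start)
            # ascending, non-overlapping, inside the scaffold
            for a, b in zip(bl, bl[1:]):
                assert a.tgt_end <= b.tgt_start
            assert bl[0].tgt_start >= 0 and bl[-1].tgt_end <= lengths[sid]
            # unaligned bases are only junction gaps and subtelomeric margins
            covered = sum(b.tgt_end - b.tgt_start for b in bl)
            assert covered >= 0.5 * lengths[sid]

    def test_poisson_coverage_moments(self):
        cfg = dataclasses.replace(SMALL_SIM, chimera_rate=0.4, n_scaffolds=150, seed=9)
        res = simulate(cfg)
        true_cov = [j["coverage"] for j in res.truth.joins if not j["chimeric"]]
        chim_cov = [j["coverage"] for j in res.truth.joins if j["chimeric"]]
        assert len(chim_cov) >= 10 and len(true_cov) >= 10
        for sample, lam in ((true_cov, cfg.lambda_true), (chim_cov, cfg.lambda_chim)):
            se = np.sqrt(lam / len(sample))
            assert abs(np.mean(sample) - lam) < 3 * se

    def test_too_few_scaffolds_rejected(self, small_sim_result):
        cfg = dataclasses.replace(SMALL_SIM, n_scaffolds=1)
        with pytest.raises(ValueError):
            fragment_and_observe(small_sim_result.karyotype, cfg)


class TestPcrOracle:
    def _truth(self):
        from karyoforge.simulate import TruthLog

        t = TruthLog()
        t.joins = [
            {"scaffold": "s", "offset": 10, "chimeric": False, "span": 2_000, "coverage": 400},
            {"scaffold": "s", "offset": 20, "chimeric": True, "span": 2_000, "coverage": 4},
            {"scaffold": "s", "offset": 30, "chimeric": False, "span": 6_000, "coverage": 400},
        ]
        return t

    def test_outcomes(self):
        t = self._truth()
        assert pcr_oracle(("s", 10), t) == "confirmed"
        assert pcr_oracle(("s", 20), t) == "refuted"
        # spans of exactly 6 kbp cannot be assayed
        assert pcr_oracle(("s", 30), t) == "untestable"

    def test_unknown_join_errors(self):
        with pytest.raises(KeyError):
            pcr_oracle(("s", 99), self._truth())


class TestBacPanel:
    def test_identity_order_monotone(self):
        from karyoforge.simulate import DerivedKaryotype

        g = generate_ancestor(one_chrom_config())
        kary = DerivedKaryotype(g)
        bacs, obs = emit_bac_panel(kary, 500_000)
        ranks = {b: r for b, _c, r in obs}
        ids = [b.id for b in bacs]
        assert [ranks[i] for i in ids] == sorted(ranks[i] for i in ids)

    def test_inversion_reverses_marker_order(self):
        from karyoforge.simulate import DerivedKaryotype

        g = generate_ancestor(one_chrom_config())
        kary = DerivedKaryotype(g)
        kary.inversion("anc1", 2_000_000, 8_000_000)
        bacs, obs = emit_bac_panel(kary, 500_000)
        inside = [
            (b.ref.start, rank)
            for b in bacs
            for bid, _c, rank in obs
            if bid == b.id and 2_000_000 <= b.ref.start < 8_000_000
        ]
        inside.sort()
        ranks = [r for _p, r in inside]
        assert ranks == sorted(ranks, reverse=True)

    def test_full_dropout_empty(self):
        from karyoforge.simulate import DerivedKaryotype

        g = generate_ancestor(one_chrom_config())
        kary = DerivedKaryotype(g)
        _bacs, obs = emit_bac_panel(kary, 500_000, np.random.default_rng(0), dropout=1.0)
        assert obs == []

    def test_oversized_spacing_rejected(self):
        from karyoforge.simulate import DerivedKaryotype

        g = generate_ancestor(one_chrom_config())
        with pytest.raises(ValueError):
            emit_bac_panel(DerivedKaryotype(g), 100_000_000)


def test_simulation_fully_deterministic():
    a = simulate(SMALL_SIM)
    b = simulate(SMALL_SIM)
    assert a.truth.to_json() == b.truth.to_json()
    assert a.blocks == b.blocks
    assert a.coverage == b.coverage
    assert a.observations == b.observations
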
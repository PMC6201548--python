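import numpy as np
import pytest
from scipy import stats as sps

from karyoforge import Genome, SeqInterval
from karyoforge.cne import (
    distance_to_mshsb_density,
    ebr_flank_contrast,
    kruskal_wallis,
    make_flank_set,
    mann_whitney_u,
    scan_1kb_windows,
)
from karyoforge.homology import EBR


@pytest.fixture
def flat_genome():
    g = Genome({"c": 100_000})
    g.set_track("CNE", {})
    g.set_track("msHSB", {})
    return g


class TestFlankSet:
    def test_window_arithmetic(self, flat_genome):
        fs = make_flank_set(SeqInterval("c", 10_000, 12_000), flat_genome)
        assert (fs.ebr.start, fs.ebr.end) == (10_000, 12_000)
        assert (fs.windows[-2].start, fs.windows[-2].end) == (6_000, 8_000)
        assert (fs.windows[-1].start, fs.windows[-1].end) == (8_000, 10_000)
        assert (fs.windows[1].start, fs.windows[1].end) == (12_000, 14_000)
        assert (fs.windows[2].start, fs.windows[2].end) == (14_000, 16_000)
        assert fs.truncated == frozenset()

    def test_short_ebr_extended(self, flat_genome):
        fs = make_flank_set(SeqInterval("c", 50_000, 50_400), flat_genome)
        assert fs.ebr.length == 2_400
        assert all(w.length == 2_400 for w in fs.windows.values())

    def test_chromosome_start_truncates_upstream(self, flat_genome):
        fs = make_flank_set(SeqInterval("c", 0, 2_000), flat_genome)
        assert fs.windows[-1] is None and fs.windows[-2] is None
        assert {-1, -2} <= set(fs.truncated)

    def test_outside_chromosome_rejected(self, flat_genome):
        with pytest.raises(ValueError):
            make_flank_set(SeqInterval("c", 99_000, 101_000), flat_genome)


class TestFlankContrast:
    def test_empty_track_degenerates_to_p_one(self, flat_genome):
        ebrs = [
            EBR(unit="c", start=20_000, end=22_000, cls="intrachromosomal"),
            EBR(unit="c", start=60_000, end=62_000, cls="fission"),
        ]
        rep = ebr_flank_contrast(ebrs, flat_genome)
        assert rep.mannwhitney[1] == 1.0
        assert rep.kruskal[1] == 1.0

    def test_oversized_ebrs_excluded(self, flat_genome):
        ebrs = [EBR(unit="c", start=0, end=99_000 + 2_000, cls="fusion")]
        with pytest.raises(ValueError):
            # the single EBR is > 100 kb, so nothing remains
            ebr_flank_contrast(ebrs, flat_genome)


class TestWindowScan:
    def test_toy_mean_bases(self):
        g = Genome({"c": 10_000})
        g.set_track("CNE", {"c": [(1_000, 2_000), (5_500, 5_600)]})
        scan = scan_1kb_windows(g, [])
        assert scan.genome_mean_bases == pytest.approx(110.0)
        assert set(scan.table["cls"]) == {"rest"}

    def test_all_windows_in_mshsb(self):
        g = Genome({"c": 10_000_000})
        g.set_track("CNE", {"c": [(0, 870_000)]})
        g.set_track("msHSB", {"c": [(0, 10_000_000)]})
        scan = scan_1kb_windows(g, [])
        assert scan.class_mean_bases["msHSB"] == pytest.approx(scan.genome_mean_bases)

    def test_partition_and_weighted_mean(self, small_clean_result):
        from karyoforge.experiments import snap_to_windows, truth_homology_map
        from karyoforge.homology import detect_ebrs

        res = small_clean_result
        hm = truth_homology_map(res.karyotype, res.config.telomere_unaligned)
        ebrs = snap_to_windows(
            detect_ebrs(hm, ref_lengths=res.ancestor.chromosomes), res.ancestor
        )
        scan = scan_1kb_windows(res.ancestor, ebrs)
        usable = scan.table[scan.table["usable"]]
        counts = usable.groupby("cls").size()
        assert counts.sum() == len(usable)
        # genome mean is the class-size weighted mean of class means
        weighted = sum(
            scan.class_mean_bases[cls] * counts.get(cls, 0)
            for cls in scan.class_mean_bases
            if counts.get(cls, 0)
        )
        assert weighted / counts.sum() == pytest.approx(scan.genome_mean_bases)

    def test_gap_rule_drops_windows(self):
        g = Genome({"c": 10_000})
        g.set_track("CNE", {"c": [(1_000, 2_000)]})
        g.set_track("gap", {"c": [(0, 1_600)]})
        scan = scan_1kb_windows(g, [])
        # window 0 fully gapped, window 1 has 60% gap -> both unusable
        assert scan.table["usable"].tolist()[:2] == [False, False]
        assert scan.table["usable"].tolist()[2:] == [True] * 8


class TestDistanceToMshsb:
    def _scan(self, densities, mshsb_mask):
        import pandas as pd

        from karyoforge.cne import WindowScanResult

        table = pd.DataFrame(
            {
                "chrom": "c",
                "start": np.arange(len(densities)) * 1000,
                "cne_bases": [int(d * 1000) for d in densities],
                "cls": ["msHSB" if m else "rest" for m in mshsb_mask],
                "usable": True,
            }
        )
        hsb = [b for b, m in zip(table["cne_bases"], mshsb_mask) if m]
        mean_b = float(np.mean(hsb)) if hsb else float("nan")
        return WindowScanResult(
            table=table,
            class_mean_bases={"msHSB": mean_b},
            class_mean_density={"msHSB": mean_b / 1000 if hsb else float("nan")},
            genome_mean_bases=float(table["cne_bases"].mean()),
            genome_mean_density=float(table["cne_bases"].mean()) / 1000,
        )

    def test_linear_scan_example(self):
        scan = self._scan([0.0, 0.0, 0.2], [False, False, True])
        d = distance_to_mshsb_density(scan, threshold=0.1)
        assert d.tolist() == [2.0, 1.0, 0.0]

    def test_unreachable_is_missing(self):
        scan = self._scan([0.0, 0.05, 0.05], [True, True, True])
        d = distance_to_mshsb_density(scan, threshold=0.1)
        assert np.isnan(d.iloc[0])

    def test_no_mshsb_errors(self):
        scan = self._scan([0.0, 0.2], [False, False])
        scan.class_mean_density = {}
        with pytest.raises(ValueError):
            distance_to_mshsb_density(scan)


class TestMannWhitney:
    def test_worked_example(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0 and p == pytest.approx(0.1)

    def test_tied_singletons(self):
        _u, p = mann_whitney_u([1], [1])
        assert p == 1.0

    def test_exact_and_normal_paths_agree(self, monkeypatch):
        from karyoforge import cne

        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(size=6)
            y = rng.normal(size=6)
            _, p_exact = mann_whitney_u(x, y)
            monkeypatch.setattr(cne, "EXACT_LIMIT", 0)
            _, p_norm = mann_whitney_u(x, y)
            monkeypatch.setattr(cne, "EXACT_LIMIT", 12)
            assert abs(p_exact - p_norm) < 0.05

    def test_matches_scipy_large_sample(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=40)
        y = rng.normal(0.5, size=60)
        for alt in ("two-sided", "greater", "less"):
            _u, p = mann_whitney_u(x, y, alternative=alt)
            p_sp = sps.mannwhitneyu(x, y, alternative=alt).pvalue
            assert p == pytest.approx(p_sp, abs=0.01)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1])


class TestKruskalWallis:
    def test_hand_computed_example(self):
        h, _p = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        assert h == pytest.approx(12 / 42 * 89.5 - 21, abs=1e-4)

    def test_all_equal_gives_zero(self):
        h, p = kruskal_wallis([[2, 2], [2, 2]])
        assert h == 0.0 and p == 1.0

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])

    def test_matches_scipy(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(size=12), rng.normal(0.3, size=15), rng.normal(size=9)]
        h, p = kruskal_wallis(groups)
        ref = sps.kruskal(*groups)
        assert h == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(3)
        ps = []
        for _ in range(400):
            groups = [rng.normal(size=12) for _ in range(3)]
            ps.append(kruskal_wallis(groups)[1])
        assert sps.kstest(ps, "uniform").pvalue > 0.01
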
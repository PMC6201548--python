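import numpy as np
import pytest

from karyoforge import Genome, SimConfig, simulate


@pytest.fixture
def toy_genome():
    """10-kb single-chromosome genome with two CNEs and one msHSB block."""
    g = Genome({"chr1": 10_000})
    g.set_track("CNE", {"chr1": [(1_000, 2_000), (5_500, 5_600)]})
    g.set_track("msHSB", {"chr1": [(0, 10_000)]})
    return g


@pytest.fixture
def rng():
    return np.random.default_rng(0)


SMALL_SIM = SimConfig(
    n_macro=2,
    n_micro=3,
    macro_length_range=(8_000_000, 10_000_000),
    micro_length_range=(3_000_000, 4_000_000),
    n_inversions=4,
    n_fusions=3,
    n_fissions=2,
    n_scaffolds=40,
    mshsb_count=3,
    seed=0,
)


@pytest.fixture(scope="session")
def small_sim_result():
    """One small deterministic simulation shared across tests."""
    return simulate(SMALL_SIM)


@pytest.fixture(scope="session")
def small_clean_result():
    import dataclasses

    return simulate(dataclasses.replace(SMALL_SIM, chimera_rate=0.0, seed=1))
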
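import pytest

from gonomir import preprocess, simlib


@pytest.fixture(scope="session")
def bundle():
    """Small deterministic reference bundle shared across tests."""
    return simlib.generate_reference(n_mirnas=20, n_pirnas=15,
                                     n_ncrna_per_class=4, seed=7)


@pytest.fixture(scope="session")
def profile():
    return simlib.SimulationProfile(depth=8000, seed=7, error_rate=0.0)


@pytest.fixture(scope="session")
def sim_trio(bundle, profile):
    """Three simulated libraries plus their truth manifests."""
    return simlib.simulate_all(bundle, profile)


@pytest.fixture(scope="session")
def tag_table(sim_trio, profile):
    records, _ = sim_trio
    table, stats = preprocess.preprocess_libraries(records, profile.adapter)
    return table, stats
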
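import pytest

from splicedissect.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_bundle():
    """Modest synthetic dataset shared by read-only tests."""
    return simulate_dataset(SimConfig(n_events=300, seed=11))


@pytest.fixture(scope="session")
def read_bundle():
    """Small dataset with haplotype sequences and truth-labelled reads."""
    return simulate_dataset(
        SimConfig(n_events=40, seed=5, reads_per_event=30), with_reads=True
    )
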
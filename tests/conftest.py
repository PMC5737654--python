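import pytest

from isotriage.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """One deterministic synthetic dataset shared across tests."""
    return simulate_dataset(SimConfig(seed=1, n_transcripts=24))


@pytest.fixture(scope="session")
def default_dataset():
    """A dataset generated under the generator's default study conditions."""
    return simulate_dataset(SimConfig(seed=11))
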
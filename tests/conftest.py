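import pytest

from polyhmt.synthetic_data import SimulationConfig, simulate_all, write_dataset


@pytest.fixture(scope="session")
def dataset():
    """One full synthetic dataset at the default study conditions."""
    return simulate_all(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def dataset_dir(dataset, tmp_path_factory):
    """The same dataset written to disk; returns the path map."""
    out = tmp_path_factory.mktemp("simdata")
    return write_dataset(dataset, out)
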
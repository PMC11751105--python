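import pytest

from selfseg.io import write_dataset
from selfseg.simulate import PedigreeConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config():
    return PedigreeConfig(seed=11, n_background_variants=60)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """One modest synthetic screen shared across tests (read-only)."""
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def dataset_dir(small_dataset, tmp_path_factory):
    """The same screen written to disk in every supported format."""
    outdir = tmp_path_factory.mktemp("dataset")
    paths = write_dataset(small_dataset, outdir)
    return paths
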
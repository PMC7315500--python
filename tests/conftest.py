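import pytest

from mirisonet.synthetic_data import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One seeded default-condition dataset shared across tests."""
    return generate_dataset(SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_prediction(default_dataset):
    from mirisonet.target_scan import predict_targets

    return predict_targets(default_dataset.mirnas, default_dataset.isoforms)
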
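import pytest

from radstab import PhantomConfig, build_feature_catalog, generate_phantom_dataset


@pytest.fixture(scope="session")
def catalog():
    return build_feature_catalog()


@pytest.fixture(scope="session")
def default_phantom(catalog):
    """One default-design synthetic dataset shared across tests."""
    return generate_phantom_dataset(PhantomConfig(seed=1234), catalog)


@pytest.fixture(scope="session")
def noiseless_phantom(catalog):
    cfg = PhantomConfig(sigma_scan=0.0, sigma_obs=0.0, obs_shift=0.0, seed=5)
    return generate_phantom_dataset(cfg, catalog)
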
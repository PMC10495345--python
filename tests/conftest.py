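import numpy as np
import pytest

from fluxqaqc.synthetic import SyntheticSiteConfig, generate_clean


@pytest.fixture(scope="session")
def site_config():
    return SyntheticSiteConfig(seed=0)


@pytest.fixture(scope="session")
def site(site_config):
    return site_config.site


@pytest.fixture(scope="session")
def clean_table(site_config):
    """One clean synthetic year, shared (read-only) across tests."""
    return generate_clean(site_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
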
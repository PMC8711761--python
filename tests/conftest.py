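import pytest

import renalcea as rc


@pytest.fixture(scope="session")
def config():
    """Base-case configuration as shipped."""
    return rc.default_config()


@pytest.fixture(scope="session")
def base_results(config):
    """A moderate base-case cohort shared across tests (both arms, CRN)."""
    return rc.run_cohort(config, 20_000, seed=1)
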
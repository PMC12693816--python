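import pytest

from triadscreen.synthetic_data import CohortConfig, generate_cohort, generate_tissue_panel


@pytest.fixture(scope="session")
def default_config():
    return CohortConfig(seed=11)


@pytest.fixture(scope="session")
def cohort(default_config):
    """One signal cohort shared across read-only tests."""
    return generate_cohort(default_config)


@pytest.fixture(scope="session")
def tissue_panel(default_config):
    return generate_tissue_panel(default_config, panel="tissues")


@pytest.fixture(scope="session")
def null_config():
    return CohortConfig(rho_target=0.0, snp_effect_pct=0.0, seed=13)


@pytest.fixture(scope="session")
def null_cohort(null_config):
    return generate_cohort(null_config)
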
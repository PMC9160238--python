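import numpy as np
import pytest

from pathmed import (
    PathModelSpec,
    default_ucc_config,
    generate_cohort,
)


@pytest.fixture(scope="session")
def ucc_config():
    return default_ucc_config()


@pytest.fixture(scope="session")
def ucc_cohort(ucc_config):
    """One discovery-calibrated cohort at the design size (complete data)."""
    return generate_cohort(ucc_config, seed=123)


@pytest.fixture(scope="session")
def big_cohort(ucc_config):
    """Large cohort for consistency checks (n=100k)."""
    return generate_cohort(ucc_config, seed=321, n=100_000)


@pytest.fixture(scope="session")
def two_mediator_spec():
    return PathModelSpec(
        exposure="prs_pt_0.5",
        mediators=("ctq_total", "cannabis_case"),
        outcome="cape_total",
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
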
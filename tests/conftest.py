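import pytest

from uroscreen import (
    AdjudicationPolicy,
    adjudicate_cohort,
    default_catalog,
    default_spec,
    generate_cohort,
)


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def policy():
    return AdjudicationPolicy()


@pytest.fixture(scope="session")
def default_cohort():
    """The calibrated 2,821-sample cohort, adjudicated; shared across tests."""
    samples = generate_cohort(default_spec(), seed=1)
    return adjudicate_cohort(samples)
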
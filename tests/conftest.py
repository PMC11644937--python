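import numpy as np
import pytest

from ehrsynth import TableTransformer, generate_reference_cohort


@pytest.fixture(scope="session")
def cohort():
    """Default 218-row synthetic cardiovascular cohort plus its ground truth."""
    return generate_reference_cohort()


@pytest.fixture(scope="session")
def cohort_table(cohort):
    return cohort[0]


@pytest.fixture(scope="session")
def fitted_transformer(cohort_table):
    return TableTransformer(cohort_table.schema, seed=0).fit(cohort_table)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
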
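import numpy as np
import pytest

import metaboplsda as mp


@pytest.fixture(scope="session")
def template():
    return mp.default_template()


@pytest.fixture(scope="session")
def cohort(template):
    """One default-size synthetic cohort (66 cases / 30 controls)."""
    return mp.generate(template, 66, 30, seed=7)


@pytest.fixture(scope="session")
def small_cohort(template):
    """A reduced cohort for fast cross-validation tests."""
    return mp.generate(template, 24, 12, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
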
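import warnings

import numpy as np
import pytest

from vfcast.simulate import SimConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_cohort():
    """One modest synthetic cohort shared across read-only tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vf, ehr, truth = simulate_cohort(SimConfig(n_eyes=400, seed=7))
    return vf, ehr, truth
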
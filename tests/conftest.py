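import numpy as np
import pytest

from relb1map import StudyConfig, run_study


@pytest.fixture(scope="session")
def study_table():
    """Full-design Monte Carlo error table at TR/T1 = 0.01, shared across tests."""
    return run_study(StudyConfig(seed=1, tr_over_t1=(0.01,)))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
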
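import numpy as np
import pytest

from burstcount import GroundTruth, simulate_study


@pytest.fixture(scope="session")
def null_study():
    """Small study with no injected effects (pure 1/f background + evoked)."""
    return simulate_study(GroundTruth.null(), n_participants=8, n_blocks=1,
                          base_reps=4, high_prev_reps=8, seed=11)


@pytest.fixture(scope="session")
def coupled_study():
    """Small study with all default ground-truth effects switched on."""
    return simulate_study(GroundTruth(), n_participants=8, n_blocks=1,
                          base_reps=4, high_prev_reps=16, seed=12)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
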
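import numpy as np
import pytest

from pmsfe import (
    SimulationConfig,
    generate_trials,
    standard_layout,
)


@pytest.fixture(scope="session")
def layout():
    return standard_layout()


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small fast dataset: 4 subjects x 4 levels x 4 trials at reduced fs."""
    cfg = SimulationConfig(
        n_subjects=4,
        trials_per_level_per_subject=4,
        fs=250.0,
        duration_s=1.4,
        seed=11,
    )
    return generate_trials(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
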
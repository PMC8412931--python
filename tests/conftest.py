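import numpy as np
import pytest

from repdyn import synth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_table():
    """Small calibrated cohort: 8 subjects, full ABCDA2 structure, 40
    repetitions per block."""
    cfg = synth.ExperimentConfig(n_subjects=8, trials_per_block=40, seed=42)
    return synth.generate_trial_table(cfg)


@pytest.fixture(scope="session")
def full_table():
    """One full-size cohort at the default study conditions."""
    cfg = synth.ExperimentConfig(seed=7)
    return synth.generate_trial_table(cfg)


@pytest.fixture(scope="session")
def tiny_experiment():
    """Time-series dataset small enough for spectral unit tests."""
    cfg = synth.ExperimentConfig(n_subjects=1, n_blocks=2, trials_per_block=16,
                                 seed=5)
    return synth.generate_experiment(cfg)


@pytest.fixture(scope="session")
def var_pair():
    return synth.CoupledSourceTruth.gamma_oscillator(coupling=0.3)
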
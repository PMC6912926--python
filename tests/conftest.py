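import numpy as np
import pytest

from finsex.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny balanced cohort (24 fish) shared by cheap structural tests."""
    return simulate_cohort(SimConfig(n_per_cell=6, seed=11))


@pytest.fixture(scope="session")
def svm_cohort():
    """n=200 balanced cohort, no treatment attenuation, fin-yellowness
    separation of 15 b* = 3x the per-pixel noise sd (noise_sd=5)."""
    return simulate_cohort(SimConfig(n_per_cell=50, treatment_male_attenuation=0.0, seed=42))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
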
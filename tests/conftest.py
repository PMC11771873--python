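import numpy as np
import pytest

from oriadapt import KernelParams, StationaryParams


@pytest.fixture(scope="session")
def stationary():
    """Reference stationary observer parameters used throughout the suite."""
    return StationaryParams(k=0.3, kappa=3.0, kappa_i=8.0)


@pytest.fixture(scope="session")
def two_peak_kernel():
    """Reference reallocation kernel (peaks at the adaptor and orthogonal)."""
    return KernelParams(variant="two_peak", k1=0.4, k2=0.15, kappa1=8.0, kappa2=3.0)


@pytest.fixture(scope="session")
def small_dataset(stationary, two_peak_kernel):
    """Reduced-scale simulated experiment shared by fast tests (24 trials/orientation)."""
    from oriadapt import ExperimentDesign, simulate_experiment

    design = ExperimentDesign(trials_per_orientation=24)
    dataset, truth = simulate_experiment(stationary, two_peak_kernel, design, rng_seed=11)
    return dataset, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
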
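import numpy as np
import pytest

from modbrain.preprocess import empirical_covariance
from modbrain.simulate import SimulationConfig, simulate_runs


def small_sim_config(seed: int, *, noise=(0.1, 0.3), t=300, dispersion=0.2) -> SimulationConfig:
    """p=40, k=4, N=30 dataset with condition effects >= 5x dispersion."""
    return SimulationConfig(
        p=40, k_true=4, t=t,
        runs_per_condition={"awake": 8, "propofol-deep": 8,
                            "ketamine-deep": 7, "sevoflurane-deep": 7},
        condition_effects={"awake": (5, 2, 2, 4), "propofol-deep": (1, 1.5, 2.5, 1),
                           "ketamine-deep": (1, 2.5, 2, 1), "sevoflurane-deep": (1, 2, 3, 1)},
        bna_dispersion=dispersion, noise_v_range=noise, seed=seed)


@pytest.fixture(scope="session")
def sim_dataset():
    """One realization of the small benchmark dataset plus its covariances."""
    runs, truth = simulate_runs(small_sim_config(42))
    covs = [empirical_covariance(r.X) for r in runs]
    return runs, truth, covs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
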
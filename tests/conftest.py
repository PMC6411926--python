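import numpy as np
import pytest

from cspfit import SimulationConfig, simulate_titration


@pytest.fixture(scope="session")
def default_series():
    """One noisy synthetic peptide-style titration with known truth."""
    return simulate_titration(SimulationConfig(true_kd=0.7, seed=11))


@pytest.fixture(scope="session")
def noiseless_series():
    """Noise-free, broadening-free series: the pipeline must invert it exactly."""
    cfg = SimulationConfig(
        true_kd=0.5, noise_H=0.0, noise_N=0.0, n_broadened=0, seed=5
    )
    return simulate_titration(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
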
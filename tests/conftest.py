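import numpy as np
import pytest

from nmdasim import NeuronConfig, default_protocol


@pytest.fixture(scope="session")
def logistic_series():
    """Trajectories of the fully chaotic logistic map x <- 4x(1-x)."""

    def make(n: int = 5000, seed: int = 0) -> np.ndarray:
        rng = np.random.default_rng(seed)
        x = rng.uniform(0.2, 0.8)
        out = np.empty(n)
        for i in range(n):
            x = 4.0 * x * (1.0 - x)
            out[i] = x
        return out

    return make


@pytest.fixture(scope="session")
def sine_series():
    """Noiseless sine sampled incommensurately with its period (no exact
    repeats, a clean limit cycle)."""
    t = np.arange(4000)
    return np.sin(2 * np.pi * t / 40.7)


@pytest.fixture()
def short_config():
    return NeuronConfig(duration_ms=2000.0)


@pytest.fixture()
def short_protocol():
    return default_protocol(2000.0, seed=7)
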
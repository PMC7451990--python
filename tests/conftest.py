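import numpy as np
import pytest

from dynstok import (
    MultiTrialTimeSeries,
    SimulationConfig,
    generate_bivariate_demo,
    generate_surrogate_model,
    simulate_trials,
)


@pytest.fixture(scope="session")
def bivariate_demo():
    """Two-node AR(1) demonstration: transient 2->1 coupling in samples 400-600."""
    return generate_bivariate_demo(seed=7)


@pytest.fixture(scope="session")
def small_surrogate():
    """Default-parameter surrogate network scaled to 5 nodes for fast tests."""
    cfg = SimulationConfig(d=5, seed=3)
    model = generate_surrogate_model(cfg)
    Y = simulate_trials(model, 100, seed=4)
    return Y, model


def stationary_diagonal_ar1(a=0.9, n=200, T=600, d=2, fs=200.0, seed=0):
    """Trials of d independent AR(1) channels with self-coefficient a."""
    rng = np.random.default_rng(seed)
    Y = np.zeros((n, d, T))
    eps = rng.standard_normal((n, d, T))
    for t in range(1, T):
        Y[:, :, t] = a * Y[:, :, t - 1] + eps[:, :, t]
    return MultiTrialTimeSeries(data=Y, fs=fs)
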
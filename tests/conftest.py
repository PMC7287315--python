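import numpy as np
import pytest

import mixrhlp as m


@pytest.fixture(scope="session")
def truth_params():
    """Benchmark two-cluster, three-regime generating model, sigma = 0.1."""
    return m.benchmark_parameters(0.1)


@pytest.fixture(scope="session")
def small_sim(truth_params):
    """A small complete simulated panel with its ground-truth labels."""
    return m.simulate(truth_params, 20, 160, seed=42)


def random_parameters(rng, K, R, d):
    """Random valid Parameters for property tests."""
    alpha = rng.dirichlet(np.ones(K))
    omega = rng.normal(0, 1.5, size=(K, R, 2))
    omega[:, -1, :] = 0.0
    beta = rng.normal(0, 1.0, size=(K, R, d + 1))
    sigma2 = rng.uniform(0.05, 0.5, size=(K, R))
    return m.Parameters(alpha, omega, beta, sigma2)
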
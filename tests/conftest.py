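import numpy as np
import pandas as pd
import pytest

from causalkit import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Moderately confounded cohort at the generator defaults (n=2000)."""
    return generate_cohort(SimulationConfig(n_subjects=2000, seed=7))


@pytest.fixture(scope="session")
def null_cohort():
    """No confounding, no effect: pure randomization."""
    return generate_cohort(SimulationConfig(
        n_subjects=5000, true_ate=0.0, confounding_strength=0.0,
        latent_strength=0.0, seed=11))


@pytest.fixture()
def chain_data():
    """Planted linear chain X1 -> T -> Y plus independent noise covariates."""
    def make(seed, n=1000):
        rng = np.random.default_rng(seed)
        x1 = rng.standard_normal(n)
        T = (x1 + rng.standard_normal(n) > 0).astype(float)
        Y = 1.0 * T + 0.5 * x1 + 0.5 * rng.standard_normal(n)
        X = pd.DataFrame(
            np.column_stack([x1, rng.standard_normal((n, 3))]),
            columns=["x1", "n1", "n2", "n3"])
        return X, T, Y
    return make
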
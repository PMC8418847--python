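import numpy as np
import pytest
from hypothesis import settings

from crccea.config import default_config

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from crccea.markov import TransitionMatrix


@pytest.fixture(scope="session")
def config():
    """The built-in base-case parameter set (secondary data, societal)."""
    return default_config()


@pytest.fixture(scope="session")
def chemo_secondary_matrix(config):
    from crccea.valuation import arm_matrices

    return arm_matrices(config, "secondary")["chemo"]


def random_valid_matrix(rng: np.random.Generator) -> TransitionMatrix:
    """A random row-stochastic matrix with the model's structure."""
    pf = rng.dirichlet(np.ones(3))
    pd_death = rng.uniform(0.0, 1.0)
    p = np.array(
        [
            pf,
            [0.0, 1.0 - pd_death, pd_death],
            [0.0, 0.0, 1.0],
        ]
    )
    return TransitionMatrix(p)
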
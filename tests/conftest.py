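import numpy as np
import pytest

from viralsir import ModelParams, ModelState

N_REF = 1e4


@pytest.fixture(scope="session")
def demo_params() -> ModelParams:
    """Reference rates used across the docs: moderate sharing, weak advertising."""
    return ModelParams(beta=0.4, beta1=0.1, alpha=0.03, b=0.02, gamma=0.002)


@pytest.fixture(scope="session")
def demo_init() -> ModelState:
    return ModelState.initial(9900.0, 100.0)


def random_theory_params(rng: np.random.Generator) -> ModelParams:
    """One random draw satisfying beta > beta1 > 0 and alpha > b > gamma."""
    beta = 10 ** rng.uniform(-1.5, 0.5)
    beta1 = beta * rng.uniform(0.05, 0.9)
    alpha = 10 ** rng.uniform(-2.0, -0.5)
    b = alpha * rng.uniform(0.15, 0.85)
    gamma = b * rng.uniform(0.05, 0.85)
    return ModelParams(beta=beta, beta1=beta1, alpha=alpha, b=b, gamma=gamma)
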
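import numpy as np
import pytest

from noddida_dde.encoding import build_scheme
from noddida_dde.forward_model import ModelParams


@pytest.fixture(scope="session")
def scheme_sde():
    return build_scheme("DDE60+0", seed=1)


@pytest.fixture(scope="session")
def scheme_dde3030():
    return build_scheme("DDE30+30", seed=1)


@pytest.fixture(scope="session")
def scheme_dde0060():
    return build_scheme("DDE0+60", seed=1)


@pytest.fixture(scope="session")
def mu_oblique():
    mu = np.array([0.3, -0.5, 0.8])
    return mu / np.linalg.norm(mu)


@pytest.fixture
def params_row1():
    """First worked-example parameter set (fiber along z)."""
    return ModelParams(f=0.730, Da=2.000, De_par=1.000, De_perp=0.300, kappa=8.000)


@pytest.fixture
def params_set_a(mu_oblique):
    """PLIC ground truth SET A (c2 = 0.98)."""
    return ModelParams(f=0.38, Da=0.50, De_par=2.10, De_perp=0.74, kappa=64.0, mu=mu_oblique)


def random_feasible_params(rng, n, mu=None, kappa_range=(0.3, 80.0)):
    """Interior points of the feasible region for round-trip style tests."""
    out = []
    for _ in range(n):
        out.append(
            ModelParams(
                f=rng.uniform(0.05, 0.95),
                Da=rng.uniform(0.1, 2.9),
                De_par=rng.uniform(0.1, 2.9),
                De_perp=rng.uniform(0.1, 2.9),
                kappa=np.exp(rng.uniform(np.log(kappa_range[0]), np.log(kappa_range[1]))),
                mu=mu if mu is not None else np.array([0.0, 0.0, 1.0]),
            )
        )
    return out
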
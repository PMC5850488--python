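import numpy as np
import pytest

from torusevo import (
    EvolutionaryModel,
    HiddenState,
    SiteClass,
    TorusPoint,
    WNParams,
    example_model,
)
from torusevo.ctmc import random_exchangeability


@pytest.fixture(scope="session")
def model3():
    """The 3-state helix/sheet/coil example model."""
    return example_model()


@pytest.fixture(scope="session")
def fig_params():
    """The WN diffusion drawn in the drift-field illustration:
    A = (1, 0.5; 0.5, 0.5), μ = (0, 0), Σ = 1.5²·I."""
    return WNParams(TorusPoint(0.0, 0.0), alpha1=1.0, alpha2=0.5, alpha3=0.5,
                    sigma1=1.5, sigma2=1.5).validate()


def _small_class(rng, mu):
    eq = rng.dirichlet(np.ones(20))
    ss = rng.dirichlet(np.ones(3))
    wnp = WNParams(TorusPoint(*mu), alpha1=float(rng.uniform(0.8, 2.0)),
                   alpha2=float(rng.uniform(0.8, 2.0)), alpha3=0.2,
                   sigma1=float(rng.uniform(0.4, 0.9)),
                   sigma2=float(rng.uniform(0.4, 0.9)))
    return SiteClass(eq, float(rng.uniform(0.5, 1.5)), ss, wnp)


@pytest.fixture(scope="session")
def model2():
    """A small random 2-state model used by enumeration oracles."""
    rng = np.random.default_rng(42)
    states = []
    for mu_pair in (((-1.0, -0.7), (1.2, 0.4)), ((-2.1, 2.3), (-1.5, 0.2))):
        states.append(
            HiddenState(_small_class(rng, mu_pair[0]), _small_class(rng, mu_pair[1]),
                        class_equilibrium=np.array([0.65, 0.35]), jump_rate=2.5)
        )
    T = np.array([[0.8, 0.2], [0.3, 0.7]])
    S = random_exchangeability(20, rng)
    V = random_exchangeability(3, rng)
    return EvolutionaryModel(states, T, S, V)


@pytest.fixture(scope="session")
def model1(model2):
    """Degenerate single-state model (sub-model of model2)."""
    return EvolutionaryModel([model2.states[0]], np.array([[1.0]]),
                             model2.global_aa_exchangeability,
                             model2.global_ss_exchangeability)
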
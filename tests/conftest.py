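import numpy as np
import pytest

from polypill.markov import MarkovModel, StateSpace


def make_random_model(
    rng: np.random.Generator,
    n_states: int = 5,
    n_cycles: int = 10,
    discount_rate: float = 0.03,
) -> MarkovModel:
    """Random valid model: Dirichlet rows, last state absorbing ('Dead')."""
    names = [f"S{i}" for i in range(n_states - 1)] + ["Dead"]
    mat = rng.dirichlet(np.ones(n_states), size=n_states)
    mat[-1] = 0.0
    mat[-1, -1] = 1.0
    costs = rng.uniform(0, 1000, size=n_states)
    utilities = rng.uniform(0, 1, size=n_states)
    costs[-1] = 0.0
    utilities[-1] = 0.0
    return MarkovModel(
        states=StateSpace(names, absorbing=["Dead"]),
        transition=mat,
        initial_distribution=np.eye(n_states)[0],
        n_cycles=n_cycles,
        costs=costs,
        utilities=utilities,
        discount_rate=discount_rate,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)


@pytest.fixture
def alive_dead_model():
    """Two states, p(Alive -> Dead) = 0.5, start all alive."""
    return MarkovModel(
        states=StateSpace(["Alive", "Dead"], absorbing=["Dead"]),
        transition=np.array([[0.5, 0.5], [0.0, 1.0]]),
        initial_distribution=np.array([1.0, 0.0]),
        n_cycles=10,
        costs=np.array([100.0, 0.0]),
        utilities=np.array([1.0, 0.0]),
        discount_rate=0.0,
    )
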
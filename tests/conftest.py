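import numpy as np
import pytest

from refpoint import (
    LayerRanges,
    compute_bounds,
    from_point_list,
    generate_landscape,
    generate_random_mdp,
)


@pytest.fixture
def triangle_problem():
    """Feasible criteria set {(0,3), (2,2), (3,0)}: (2,2) is an unsupported-ish compromise."""
    return from_point_list([(0, 3), (2, 2), (3, 0)])


@pytest.fixture
def triangle_bounds(triangle_problem):
    return compute_bounds(triangle_problem)


@pytest.fixture
def square_problem():
    """Feasible criteria set {(0,4), (4,0), (1,1)}: (1,1) is non-dominated but unsupported."""
    return from_point_list([(0, 4), (4, 0), (1, 1)])


@pytest.fixture
def tiny_mdp():
    return generate_random_mdp(n_states=2, n_actions=2, horizon=3, seed=11)


def tiny_landscape(rows=4, cols=4, K=3, seed=0, n_species=3):
    return generate_landscape(rows, cols, n_species=n_species, seed=seed, K=K)


@pytest.fixture
def small_landscape():
    return tiny_landscape()
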
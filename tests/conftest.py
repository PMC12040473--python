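"""Shared fixtures: the two built-in oscillators and their analyses.

Steady states and loop decompositions are solved once per session; they are
deterministic, so sharing them across tests only saves time.
"""

import numpy as np
import pytest

from bondosc import (Network, Reaction, Species, build_illustrative,
                     build_selkov, solve_closed_loop, split_loop)


@pytest.fixture(scope="session")
def illustrative():
    return build_illustrative()


@pytest.fixture(scope="session")
def illustrative_steady(illustrative):
    net, loop = illustrative
    return solve_closed_loop(net, loop)


@pytest.fixture(scope="session")
def illustrative_decomp(illustrative, illustrative_steady):
    net, loop = illustrative
    return split_loop(net, loop, illustrative_steady)


@pytest.fixture(scope="session")
def selkov():
    return build_selkov()


@pytest.fixture(scope="session")
def selkov_steady(selkov):
    net, loop = selkov
    return solve_closed_loop(net, loop)


@pytest.fixture(scope="session")
def selkov_decomp(selkov, selkov_steady):
    net, loop = selkov
    return split_loop(net, loop, selkov_steady)


def make_random_network(rng: np.random.Generator) -> Network:
    """Small random closed network with integer stoichiometry (oracle food)."""
    n_s = int(rng.integers(3, 6))
    n_r = int(rng.integers(2, 5))
    names = [f"S{i}" for i in range(n_s)]
    species = [Species(nm, K=float(rng.uniform(0.5, 2.0)),
                       amount=float(rng.uniform(0.2, 2.0))) for nm in names]
    reactions = []
    for j in range(n_r):
        k = rng.permutation(n_s)
        nr = int(rng.integers(1, 3))
        npd = int(rng.integers(1, 3))
        reactants = {names[i]: int(rng.integers(1, 3)) for i in k[:nr]}
        products = {names[i]: int(rng.integers(1, 3)) for i in k[nr:nr + npd]}
        reactions.append(Reaction(f"r{j}", kappa=float(rng.uniform(0.5, 2.0)),
                                  reactants=reactants, products=products))
    return Network(species, reactions)
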
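import numpy as np
import pytest

import entroflux as ef


@pytest.fixture(scope="session")
def toy_network():
    return ef.toy_tic_network()


@pytest.fixture(scope="session")
def toy_split(toy_network):
    return ef.split_reversible(toy_network)


@pytest.fixture(scope="session")
def parallel_split():
    return ef.split_reversible(ef.parallel_paths_network())


@pytest.fixture(scope="session")
def flow_network():
    """Small seeded random flow network with one-gene-per-reaction GPRs."""
    return ef.random_flow_network(seed=1)


@pytest.fixture
def mixed_network():
    """4 reactions, one reversible, for split/round-trip checks:
    uptake -> A, A <-> B (reversible), B -> A (cycle), B -> out."""
    S = np.array([
        [1., -1., 1., 0.],
        [0., 1., -1., -1.],
    ])
    return ef.MetabolicNetwork(
        metabolite_ids=["A", "B"],
        reaction_ids=["r1", "r2", "r3", "r4"],
        S=S,
        lower_bound=np.array([0., -10., 0., 0.]),
        upper_bound=np.array([10., 10., 10., 10.]),
        gpr_rules=["gA", "gB", "gC", "gD"],
        subsystems=["Exchange", "Core", "Core", "Exchange"],
    )


def preset_rx(split, name):
    return ef.map_expression(split, ef.tic_expression_preset(name))
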
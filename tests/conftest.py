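import numpy as np
import pytest

from condmd.engine import EngineParams, SimulationState, Topology
from condmd.model import CGModel, InteractionTable, make_sequence


@pytest.fixture(scope="session")
def weak_model():
    return CGModel(InteractionTable(0.5, 5.0, coupled=True))


@pytest.fixture(scope="session")
def homopolymer_model():
    return CGModel(InteractionTable(0.66, 0.66))


@pytest.fixture
def free_walkers():
    """200 non-interacting single-bead 'chains' in a huge box."""
    n = 200
    rng = np.random.default_rng(7)
    box = np.array([1000.0] * 3)
    topo = Topology(n, 1, np.full(n, 2, dtype=np.int8))
    pos = rng.uniform(100.0, 900.0, (n, 3))
    state = SimulationState(pos, np.zeros((n, 3), dtype=np.int64),
                            np.zeros((n, 3)), box, topo)
    # negligible attraction so the walkers are effectively free
    model = CGModel(InteractionTable(1e-9, 1e-9))
    return state, model


def random_chain_state(n_chains=4, chain_len=10, box_edge=12.0, seed=0,
                       patterning="uniform"):
    """Small random (possibly overlapping) chain system for force oracles."""
    rng = np.random.default_rng(seed)
    if patterning == "uniform" and chain_len == 39:
        seq = make_sequence("uniform")
        roles = np.tile(seq.roles_array(), n_chains)
    else:
        roles = rng.integers(0, 3, n_chains * chain_len).astype(np.int8)
    box = np.array([box_edge] * 3)
    pos = np.empty((n_chains * chain_len, 3))

    def min_image_dist(p, others):
        d = others - p
        d -= box_edge * np.rint(d / box_edge)
        return np.sqrt((d * d).sum(axis=1).min())

    k = 0
    for c in range(n_chains):
        p = rng.uniform(0, box_edge, 3)
        for b in range(chain_len):
            # keep separations above the engine's deep-overlap clamp (0.3)
            for _ in range(200):
                if k == 0 or min_image_dist(np.mod(p, box_edge), pos[:k]) > 0.55:
                    break
                d = rng.normal(size=3)
                p = p + 0.5 * d / np.linalg.norm(d)
            pos[k] = np.mod(p, box_edge)
            k += 1
            d = rng.normal(size=3)
            p = p + d / np.linalg.norm(d)
    topo = Topology(n_chains, chain_len, roles)
    vel = rng.normal(0, 1, pos.shape)
    return SimulationState(pos, np.zeros_like(pos, dtype=np.int64), vel, box, topo)
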
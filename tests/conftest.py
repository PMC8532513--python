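import numpy as np
import pytest

from evogem.fba import MediaSpec
from evogem.gpr import parse_gpr
from evogem.panmodel import Metabolite, PanModel, Reaction
from evogem.synthetic import generate_ec_world, generate_pan_network


@pytest.fixture(scope="session")
def world():
    """Default synthetic world used across integration tests."""
    return generate_pan_network(4, 16, 0.3, 0.3, seed=1)


@pytest.fixture(scope="session")
def world_traits(world):
    return world.simulate_traits()


@pytest.fixture(scope="session")
def ec_toy():
    return generate_ec_world()


def linear_chain_model():
    """EX_S (uptake 10) -> transport -> biomass consuming 2 P: optimum 5."""
    mets = [
        Metabolite("s_e", compartment="e"),
        Metabolite("p_c"),
        Metabolite("bm_c"),
    ]
    reactions = [
        Reaction("EX_S", {"s_e": -1.0}, -10.0, 1000.0),
        Reaction("T", {"s_e": -1.0, "p_c": 1.0}, 0.0, 1000.0, parse_gpr("G_T")),
        Reaction("BIO", {"p_c": -2.0, "bm_c": 1.0}, 0.0, 1000.0),
        Reaction("EX_BM", {"bm_c": -1.0}, 0.0, 1000.0),
    ]
    return PanModel(mets, reactions, "BIO")


@pytest.fixture
def chain_model():
    return linear_chain_model()


@pytest.fixture
def chain_media():
    return MediaSpec({"EX_S": (-10.0, 1000.0)}, name="chain")


def random_gpr(rng: np.random.Generator, genes, depth=0):
    """Random GPR tree over the given gene pool (for oracle tests)."""
    if depth >= 3 or rng.random() < 0.4:
        return str(rng.choice(genes))
    op = " and " if rng.random() < 0.5 else " or "
    k = int(rng.integers(2, 4))
    parts = [f"({random_gpr(rng, genes, depth + 1)})" for _ in range(k)]
    return op.join(parts)
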
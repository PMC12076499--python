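import numpy as np
import pytest

from crnode.crn_model import (
    FlowConditions,
    Reaction,
    ReactionNetwork,
    Species,
    fmoc_oscillator,
    toy_flow_conditions,
    toy_initial_state,
)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def ab_network():
    """A -> B, first order, k = 2."""
    return ReactionNetwork(
        species=[Species(1, "A"), Species(2, "B")],
        reactions=[Reaction("decay", reactants={1: 1}, products={2: 1}, rate_key="k")],
        kappa={"k": 2.0},
    )


@pytest.fixture
def autocatalytic_network():
    """A + B -> 2B, k = 1."""
    return ReactionNetwork(
        species=[Species(1, "A"), Species(2, "B")],
        reactions=[
            Reaction("auto", reactants={1: 1, 2: 1}, products={2: 2}, rate_key="k")
        ],
        kappa={"k": 1.0},
    )


@pytest.fixture
def oscillator():
    return fmoc_oscillator("toy_oscillator")


@pytest.fixture
def toy_flow():
    return toy_flow_conditions()


@pytest.fixture
def toy_y0():
    return toy_initial_state()


def oracle_oscillator_rhs(kappa: dict, y: np.ndarray) -> np.ndarray:
    """Literal term-by-term transcription of the 7-species oscillator ODEs.

    Kept independent of the generic builder on purpose: it is the oracle the
    builder is checked against.
    """
    y1, y2, y3, y4, y5, y6, y7 = y
    r_tr = kappa["k_tr"] * y2 * y5
    r_ac = kappa["k_ac"] * y1 * y2
    r_i1 = kappa["k_inh1"] * y1 * y3
    r_i2 = kappa["k_inh2"] * y1 * y4
    return np.array(
        [
            r_tr + r_ac - r_i1 - r_i2,  # piperidine
            -r_tr - r_ac,  # fuel ester
            -r_i1,  # fast inhibitor
            -r_i2,  # slow inhibitor
            0.0,  # constant base catalyst
            r_tr + r_ac,  # dibenzofulvene
            r_i1 + r_i2,  # acetylated product
        ]
    )
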
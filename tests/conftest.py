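import numpy as np
import pytest

import gutcom as gc
from gutcom.core import GEM, Metabolite, Reaction

SHARED = ["glucan", "ac", "prop", "succ", "but", "form", "h2", "co2", "ch4"]


@pytest.fixture(scope="session")
def toy_gems():
    return gc.make_toy_gems()


@pytest.fixture(scope="session")
def study_conditions():
    """(diet, abundance scenarios, absorption) of the study."""
    return gc.make_fixtures()


@pytest.fixture(scope="session")
def make_community(toy_gems):
    """Factory: build a community from species names, sharing every
    exchange metabolite present in any chosen member."""

    def build(*species):
        members = [toy_gems[s] for s in species]
        shared = [m for m in SHARED if any(g.has_metabolite(m) for g in members)]
        return gc.build_community(members, shared=shared)

    return build


@pytest.fixture(scope="session")
def triangle_model():
    """1-metabolite model whose feasible set is a 2-simplex: R1 -> A with
    v1 <= 1, R2/R3 drain A, so (v2, v3) is uniform on {v2,v3>=0, v2+v3<=1}
    and v1 = v2 + v3."""
    return GEM(
        "triangle",
        [Metabolite("A", "A", "c")],
        [
            Reaction("R1", {"A": 1}, lower_bound=0, upper_bound=1, is_exchange=True),
            Reaction("R2", {"A": -1}, lower_bound=0, upper_bound=1000, is_exchange=True),
            Reaction("R3", {"A": -1}, lower_bound=0, upper_bound=1000, is_exchange=True),
        ],
    )


@pytest.fixture(scope="session")
def triangle_sample(triangle_model):
    """One 50,000-point hit-and-run sample of the triangle polytope,
    shared across tests (deterministic, seed 7)."""
    from gutcom.sampling import sample_fluxes

    return sample_fluxes(triangle_model, 50000, seed=7)


@pytest.fixture
def chain_model():
    """Linear chain A_ext -> A -> B -> B_ext with uptake capped at 10."""
    mets = [
        Metabolite("A_ext", compartment="e"),
        Metabolite("A", compartment="c"),
        Metabolite("B", compartment="c"),
        Metabolite("B_ext", compartment="e"),
    ]
    rxns = [
        Reaction("EX_A", {"A_ext": -1}, lower_bound=-10, upper_bound=0, is_exchange=True),
        Reaction("T_A", {"A_ext": -1, "A": 1}, lower_bound=0),
        Reaction("CONV", {"A": -1, "B": 1}, lower_bound=0),
        Reaction("T_B", {"B": -1, "B_ext": 1}, lower_bound=0),
        Reaction("EX_B", {"B_ext": -1}, lower_bound=0, upper_bound=1000, is_exchange=True),
    ]
    return GEM("chain", mets, rxns)
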
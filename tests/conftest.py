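"""Shared fixture models.

All fixtures are built in memory; nothing is read from disk except where a
test exercises the readers themselves (those write to tmp_path first).
"""

import math

import pytest
from hypothesis import settings

from mento.model_io import MetabolicModel, Metabolite, Reaction, detect_exchanges

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


def build_model(model_id, metabolites, reactions, biomass_id, genes=()):
    model = MetabolicModel(
        id=model_id,
        metabolites=metabolites,
        reactions=reactions,
        biomass_reaction_id=biomass_id,
        genes=set(genes),
    )
    detect_exchanges(model)
    model.validate()
    return model


@pytest.fixture
def yield_toy():
    """Biomass consumes A one-to-one; A enters through a single exchange.

    With uptake magnitude u the biomass optimum is exactly u.
    """
    return build_model(
        "yield_toy",
        [Metabolite("A", compartment="e", molar_mass=18.0)],
        [
            Reaction("EX_A", {"A": -1.0}, is_exchange=True),
            Reaction("biomass", {"A": -1.0}, lower_bound=0.0, upper_bound=1000.0),
        ],
        "biomass",
    )


def _transport_chain(nut, mass):
    """Exchange + irreversible transport for one external nutrient."""
    mets = [
        Metabolite(f"{nut}_e", compartment="e", molar_mass=mass),
        Metabolite(f"{nut}_c", compartment="c", molar_mass=mass),
    ]
    rxns = [
        Reaction(f"EX_{nut}", {f"{nut}_e": -1.0}, is_exchange=True),
        Reaction(f"T_{nut}", {f"{nut}_e": -1.0, f"{nut}_c": 1.0}, lower_bound=0.0),
    ]
    return mets, rxns


def _conversion_toy(with_conversions):
    """Biomass needs A and B; C converts into either when enabled.

    Masses A=18, B=18, C=60: with the C conversions present the minimal
    medium is the single compound C; without them it is {A, B}.
    """
    mets, rxns = [], []
    for nut, mass in (("A", 18.0), ("B", 18.0), ("C", 60.0)):
        m, r = _transport_chain(nut, mass)
        mets += m
        rxns += r
    if with_conversions:
        rxns.append(Reaction("C_to_A", {"C_c": -1.0, "A_c": 1.0}, lower_bound=0.0))
        rxns.append(Reaction("C_to_B", {"C_c": -1.0, "B_c": 1.0}, lower_bound=0.0))
    rxns.append(
        Reaction(
            "biomass",
            {"A_c": -1.0, "B_c": -1.0},
            lower_bound=0.0,
            upper_bound=1000.0,
        )
    )
    return build_model(
        "conv_toy" if with_conversions else "conv_toy_nc", mets, rxns, "biomass"
    )


@pytest.fixture
def conversion_toy():
    return _conversion_toy(with_conversions=True)


@pytest.fixture
def no_conversion_toy():
    return _conversion_toy(with_conversions=False)


@pytest.fixture
def autotroph_toy():
    """Grows with zero uptake: an internal cycle emits the biomass precursor.

    One importable but useless nutrient keeps the exchange set nonempty.
    """
    mets = [
        Metabolite("cyc_a", compartment="c", molar_mass=50.0),
        Metabolite("cyc_b", compartment="c", molar_mass=50.0),
        Metabolite("X", compartment="c", molar_mass=30.0),
    ]
    rxns = [
        Reaction("R1", {"cyc_a": -1.0, "cyc_b": 1.0}, lower_bound=0.0),
        Reaction(
            "R2", {"cyc_b": -1.0, "cyc_a": 1.0, "X": 1.0}, lower_bound=0.0
        ),
        Reaction("biomass", {"X": -1.0}, lower_bound=0.0, upper_bound=1000.0),
    ]
    m, r = _transport_chain("junk", 99.0)
    return build_model("autotroph", mets + m, rxns + r, "biomass")


@pytest.fixture
def unbounded_toy():
    """A flux loop with infinite bounds makes the biomass LP unbounded."""
    inf = math.inf
    mets = [
        Metabolite("a", compartment="c"),
        Metabolite("b", compartment="c"),
        Metabolite("x", compartment="c"),
    ]
    rxns = [
        Reaction("L1", {"a": -1.0, "b": 1.0, "x": 1.0}, lower_bound=0.0, upper_bound=inf),
        Reaction("L2", {"b": -1.0, "a": 1.0}, lower_bound=0.0, upper_bound=inf),
        Reaction("biomass", {"x": -1.0}, lower_bound=0.0, upper_bound=inf),
    ]
    return build_model("unbounded", mets, rxns, "biomass")


@pytest.fixture
def gpr_toy():
    """Conversion toy with gene rules on the C conversions.

    ``C_to_A`` needs g1 AND g2 (complex); ``C_to_B`` needs g1 OR g3
    (isozymes); transports carry no genes.
    """
    model = _conversion_toy(with_conversions=True)
    model.reaction("C_to_A").gpr = "g1 and g2"
    model.reaction("C_to_B").gpr = "g1 or g3"
    model.genes = {"g1", "g2", "g3"}
    model.id = "gpr_toy"
    return model


@pytest.fixture
def swap_toy():
    """Two equal-mass interchangeable sole nitrogen-like sources.

    Biomass needs P0 and P1.  P0 can come from either of two 100 g/mol
    compounds (the planted swap pair); P1 only from a 60.05 g/mol
    compound.  The canonical MINENV picks the lexicographically smaller of
    the pair; the swap check must report exactly the planted exchange.
    """
    mets, rxns = [], []
    for nut, mass in (("alpha", 100.0), ("beta", 100.0), ("gamma", 60.05)):
        m, r = _transport_chain(nut, mass)
        mets += m
        rxns += r
    mets += [
        Metabolite("P0", compartment="c"),
        Metabolite("P1", compartment="c"),
    ]
    rxns += [
        Reaction("C_alpha", {"alpha_c": -1.0, "P0": 1.0}, lower_bound=0.0),
        Reaction("C_beta", {"beta_c": -1.0, "P0": 1.0}, lower_bound=0.0),
        Reaction("C_gamma", {"gamma_c": -1.0, "P1": 1.0}, lower_bound=0.0),
        Reaction(
            "biomass",
            {"P0": -1.0, "P1": -1.0},
            lower_bound=0.0,
            upper_bound=1000.0,
        ),
    ]
    return build_model("swap_toy", mets, rxns, "biomass")
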
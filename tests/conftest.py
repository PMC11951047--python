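"""Shared fixtures: synthetic models at several promiscuity structures."""

import pytest

from coral.core import EnzymeRecord, EnzymeTable, Metabolite, PoolConfig, Reaction, StoichModel
from coral.fixtures import FixtureSpec, curated_fixture, make_fixture
from coral.io import merge_underground
from coral.restructure import restructure


@pytest.fixture(scope="session")
def toy_triplet():
    """A mixed fixture: promiscuous enzymes, complexes, isozymes, underground."""
    spec = FixtureSpec(
        n_steps=4,
        promiscuity_profile=(1, 2, 3),
        n_underground=2,
        and_fraction=0.3,
        or_fraction=0.3,
        seed=3,
    )
    return make_fixture(spec)


@pytest.fixture(scope="session")
def toy_coral(toy_triplet):
    model, table, und = toy_triplet
    merged = merge_underground(model, und)
    return restructure(merged, table, ordering="chain")


def build_curated(name, ordering="chain", pool=None):
    model, table, _ = curated_fixture(name)
    return restructure(model, table, pool, ordering=ordering)


@pytest.fixture(scope="session")
def direct_transfer_coral():
    return build_curated("direct_transfer")


@pytest.fixture(scope="session")
def or_isozyme_coral():
    return build_curated("or_isozyme")


def two_subpool_closed_form_model():
    """One enzyme, two activities with kcats 100 and 10 per hour, identical
    stoichiometry; the enzyme pool will be pinned to 1 mmol in tests."""
    m = StoichModel(id="closed_form")
    for mid in ("A", "B"):
        m.add_metabolite(Metabolite(id=mid, compartment="c"))
    m.add_reaction(Reaction(id="EX_A", stoichiometry={"A": -1.0},
                            lower_bound=-1000.0, upper_bound=0.0))
    m.add_reaction(Reaction(id="R1", stoichiometry={"A": -1.0, "B": 1.0}, gpr="g"))
    m.add_reaction(Reaction(id="R2", stoichiometry={"A": -1.0, "B": 1.0}, gpr="g"))
    m.add_reaction(Reaction(id="BIOMASS", stoichiometry={"B": -1.0}))
    m.objective_id = "BIOMASS"
    m.genes = ["g"]
    table = EnzymeTable()
    rec = EnzymeRecord("E", ("g",), mw=1.0)
    rec.kcats[("R1", "fwd")] = 100.0
    rec.kcats[("R2", "fwd")] = 10.0
    table.add(rec)
    # generous budget so only the pinned pool binds
    pool = PoolConfig(ptot=40.0, sigma=0.5, f=0.5)
    return restructure(m, table, pool, ordering="chain")
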
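import pytest

from oleaflux.core import GprRule, MetabolicModel, Metabolite, Reaction
from oleaflux.synthetic import (
    MiniAlpinaSpec,
    generate_mini_alpina,
    mini_alpina_media,
)


@pytest.fixture(scope="session")
def mini():
    """The default curated synthetic model and its ground-truth record."""
    return generate_mini_alpina()


@pytest.fixture(scope="session")
def mini_model(mini):
    return mini[0]


@pytest.fixture(scope="session")
def mini_truth(mini):
    return mini[1]


@pytest.fixture(scope="session")
def media():
    """(MG, YE) medium presets for the synthetic model."""
    return mini_alpina_media()


@pytest.fixture(scope="session")
def mini_connected():
    """Mini model without the catabolically orphaned sugar (gap-free)."""
    return generate_mini_alpina(MiniAlpinaSpec(include_orphan_sugar=False))[0]


def make_chain_model(uptake=1.0):
    """EX_a -> a[e] -> a[c] -> biomass, unit stoichiometry."""
    model = MetabolicModel("chain")
    model.add_metabolite(Metabolite("a[e]", compartment="e"))
    model.add_metabolite(Metabolite("a[c]", compartment="c"))
    model.add_reaction(
        Reaction("EX_a", stoichiometry={"a[e]": -1.0},
                 lower_bound=-uptake, upper_bound=1000.0, rtype="exchange")
    )
    model.add_reaction(
        Reaction("T_a", stoichiometry={"a[e]": -1.0, "a[c]": 1.0},
                 lower_bound=0.0, upper_bound=1000.0, rtype="transport")
    )
    model.add_reaction(
        Reaction("BIO", stoichiometry={"a[c]": -1.0},
                 lower_bound=0.0, upper_bound=1000.0)
    )
    model.objective_id = "BIO"
    return model


def make_branched_model():
    """Competing-yield toy: substrate converts through two routes with
    different biomass yields plus a byproduct sink."""
    model = MetabolicModel("branched")
    for met, comp in [("s[e]", "e"), ("s[c]", "c"), ("p[c]", "c"), ("q[c]", "c")]:
        model.add_metabolite(Metabolite(met, compartment=comp))
    model.add_reaction(Reaction("EX_s", stoichiometry={"s[e]": -1.0},
                                lower_bound=-1.0, upper_bound=1000.0,
                                rtype="exchange"))
    model.add_reaction(Reaction("T_s", stoichiometry={"s[e]": -1.0, "s[c]": 1.0},
                                lower_bound=0.0, upper_bound=1000.0,
                                rtype="transport"))
    model.add_reaction(Reaction("HIGH", stoichiometry={"s[c]": -1.0, "p[c]": 2.0},
                                lower_bound=0.0, upper_bound=0.6))
    model.add_reaction(Reaction("LOW", stoichiometry={"s[c]": -1.0, "p[c]": 1.0,
                                                      "q[c]": 1.0},
                                lower_bound=0.0, upper_bound=1000.0))
    model.add_reaction(Reaction("SINK_q", stoichiometry={"q[c]": -1.0},
                                lower_bound=0.0, upper_bound=1000.0))
    model.add_reaction(Reaction("BIO", stoichiometry={"p[c]": -1.0},
                                lower_bound=0.0, upper_bound=1000.0))
    model.objective_id = "BIO"
    return model


def make_parallel_model():
    """Two equivalent parallel branches sharing a unit of flux."""
    model = MetabolicModel("parallel")
    for met, comp in [("s[e]", "e"), ("s[c]", "c"), ("p[c]", "c")]:
        model.add_metabolite(Metabolite(met, compartment=comp))
    model.add_reaction(Reaction("EX_s", stoichiometry={"s[e]": -1.0},
                                lower_bound=-1.0, upper_bound=1000.0,
                                rtype="exchange"))
    model.add_reaction(Reaction("T_s", stoichiometry={"s[e]": -1.0, "s[c]": 1.0},
                                lower_bound=0.0, upper_bound=1000.0,
                                rtype="transport"))
    model.add_reaction(Reaction("P1", stoichiometry={"s[c]": -1.0, "p[c]": 1.0},
                                lower_bound=0.0, upper_bound=1000.0,
                                gpr=GprRule("gP")))
    model.add_reaction(Reaction("Q1", stoichiometry={"s[c]": -1.0, "p[c]": 1.0},
                                lower_bound=0.0, upper_bound=1000.0,
                                gpr=GprRule("gQ")))
    model.add_reaction(Reaction("BIO", stoichiometry={"p[c]": -1.0},
                                lower_bound=0.0, upper_bound=1000.0))
    model.objective_id = "BIO"
    return model


@pytest.fixture
def chain_model():
    return make_chain_model()


@pytest.fixture
def branched_model():
    return make_branched_model()


@pytest.fixture
def parallel_model():
    return make_parallel_model()


@pytest.fixture(scope="session")
def mg_conditioned(mini_model, media):
    from oleaflux.fba import apply_medium

    return apply_medium(mini_model, media[0])


@pytest.fixture(scope="session")
def production_reference(mg_conditioned):
    """FBA reference at the production condition (growth pinned, ARA max)."""
    from oleaflux.fba import solve_fba_fixed_growth

    sol = solve_fba_fixed_growth(mg_conditioned, 0.03, "EX_ara")
    assert sol.optimal
    return sol


@pytest.fixture(scope="session")
def me_moma_solution(mg_conditioned, production_reference, mini):
    """MOMA solution for the malic-enzyme knockout (shared: it is the most
    expensive solve in the suite)."""
    from oleaflux.moma import solve_moma

    truth = mini[1]
    sol = solve_moma(mg_conditioned, production_reference,
                     knockout_genes=[truth.me_gene])
    assert sol.optimal
    return sol
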
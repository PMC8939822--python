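import cobra
import pytest

from fluxmark import (
    FluxBiomarkerAnalysis,
    apply_medium,
    generate_expression_profiles,
    generate_toy_network,
)
from fluxmark.synthetic import ExpressionProgramSpec, ToyNetworkSpec


def build_model(reactions, objective, name="test"):
    """Assemble a cobra model from (id, {met: coeff}, lb, ub, gpr) tuples.

    Metabolite compartments are taken from the id suffix after the last
    underscore; a ``pseudo_class`` note is derived from BiGG-style prefixes
    by the package itself.
    """
    model = cobra.Model(name)
    mets: dict[str, cobra.Metabolite] = {}
    built = []
    for rid, stoich, lb, ub, gpr in reactions:
        rxn = cobra.Reaction(rid, lower_bound=lb, upper_bound=ub)
        built.append((rxn, stoich, gpr))
    model.add_reactions([r for r, _, _ in built])
    for rxn, stoich, gpr in built:
        resolved = {}
        for mid, coeff in stoich.items():
            if mid not in mets:
                comp = mid.rsplit("_", 1)[-1] if "_" in mid else "c"
                mets[mid] = cobra.Metabolite(mid, compartment=comp)
                model.add_metabolites([mets[mid]])
            resolved[mets[mid]] = coeff
        rxn.add_metabolites(resolved)
        if gpr:
            rxn.gene_reaction_rule = gpr
    model.reactions.get_by_id(objective).notes["pseudo_class"] = "biomass"
    model.objective = objective
    return model


@pytest.fixture
def chain_model():
    """EX_a(lb -10) -> transport -> biomass; optimum 10."""
    return build_model([
        ("EX_a", {"a_e": -1.0}, -10.0, 1000.0, ""),
        ("T_a", {"a_e": -1.0, "a_c": 1.0}, 0.0, 1000.0, "g1"),
        ("BIOMASS", {"a_c": -1.0}, 0.0, 1000.0, ""),
    ], "BIOMASS")


@pytest.fixture(scope="session")
def toy():
    """Default synthetic network with its ground truth."""
    return generate_toy_network(ToyNetworkSpec())


@pytest.fixture(scope="session")
def toy_profiles(toy):
    _, truth = toy
    return generate_expression_profiles(truth, ExpressionProgramSpec())


@pytest.fixture(scope="session")
def toy_open(toy):
    """The synthetic model with its full medium applied."""
    model, truth = toy
    return apply_medium(model, truth.medium)


@pytest.fixture(scope="session")
def fitted_panel(toy, toy_profiles):
    """The full 4-line integration + biomarker fit (computed once)."""
    model, truth = toy
    return FluxBiomarkerAnalysis(model, toy_profiles,
                                 medium=truth.medium).fit()
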
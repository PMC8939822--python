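"""Expression integration: GIMME, OR expansion, TRFBA, C_brk, sweep."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fluxmark import (
    ConfigError,
    ExpressionProfile,
    IntegrationConfig,
    apply_trfba,
    convert_to_irreversible,
    expand_or_gprs,
    fba,
    find_c_brk,
    gimme_reduce,
    stepwise_sweep,
)
from fluxmark.fba import assert_steady_state, slim_growth
from fluxmark.integration import (
    gimme_threshold,
    gpr_conjuncts,
    prepare_for_trfba,
    reaction_expression,
)
from fluxmark.screens import evaluate_gpr
from fluxmark.synthetic import ExpressionProgramSpec, generate_expression_profiles

from .conftest import build_model


# --------------------------------------------------------------------------
# reaction expression and GIMME
# --------------------------------------------------------------------------

def test_threshold_uses_linear_interpolation():
    profile = ExpressionProfile({"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0}, "t")
    assert gimme_threshold(profile, 25.0) == pytest.approx(1.75)


@pytest.mark.parametrize("rule, expected", [
    ("g1 and g2", 2.0),          # min over AND
    ("g1 or g2", 5.0),           # max over OR
    ("(g1 and g2) or g3", 3.0),
    ("", math.inf),              # orphan: no evidence against
    ("g_missing or g1", math.inf),
])
def test_reaction_expression_min_and_max_or(rule, expected):
    levels = {"g1": 5.0, "g2": 2.0, "g3": 3.0}
    assert reaction_expression(rule, levels) == expected


def _two_route_model():
    """Two dispensable parallel routes to biomass, each gene-associated."""
    return build_model([
        ("EX_a", {"a_e": -1.0}, -10.0, 1000.0, ""),
        ("HI", {"a_e": -1.0, "p_c": 1.0}, 0.0, 1000.0, "ghi"),
        ("LO", {"a_e": -1.0, "p_c": 1.0}, 0.0, 1000.0, "glo"),
        ("BIOMASS", {"p_c": -1.0}, 0.0, 1000.0, ""),
    ], "BIOMASS")


def test_gimme_removes_low_expression_dispensable_route():
    model = _two_route_model()
    profile = ExpressionProfile({"ghi": 100.0, "glo": 1.0}, "t")
    reduced = gimme_reduce(model, profile, IntegrationConfig(gimme_percentile=50))
    assert "LO" not in [r.id for r in reduced.reactions]
    assert slim_growth(reduced) >= 0.9 * slim_growth(model) - 1e-6
    # exhaustive check on the toy: of the subsets keeping >=90% growth,
    # dropping exactly the low route is the one GIMME's objective prefers
    assert "HI" in [r.id for r in reduced.reactions]


def test_gimme_keeps_everything_above_threshold(toy, toy_profiles):
    model, truth = toy
    from fluxmark import apply_medium
    base = apply_medium(model, truth.medium)
    reduced = gimme_reduce(base, toy_profiles[0])
    assert len(reduced.reactions) == len(base.reactions)


def test_gimme_zero_program_prunes_pathway(toy):
    """A pathway whose program multiplier is 0 is cut by GIMME."""
    model, truth = toy
    from fluxmark import apply_medium
    base = apply_medium(model, truth.medium)
    redundant = [p for routes in truth.precursor_routes.values()
                 if len(routes) > 1 for p in routes]
    victim = redundant[0]
    programs = tuple(
        {p: (0.0 if p == victim else 1.0) for p in truth.pathway_genes}
        for _ in range(1))
    profile = generate_expression_profiles(
        truth, ExpressionProgramSpec(n_lines=1, programs=programs))[0]
    reduced = gimme_reduce(base, profile)
    remaining = {r.id for r in reduced.reactions}
    # orphan steps (empty GPR) carry no expression evidence and stay
    victim_internal = [
        rid for rid in truth.pathway_reactions[victim]
        if not rid.startswith("EX_")
        and base.reactions.get_by_id(rid).gene_reaction_rule
    ]
    assert victim_internal
    assert not remaining & set(victim_internal)


# --------------------------------------------------------------------------
# OR expansion
# --------------------------------------------------------------------------

@pytest.mark.parametrize("rule, expected", [
    ("g1 or g2", [{"g1"}, {"g2"}]),
    ("(g1 and g2) or g3", [{"g1", "g2"}, {"g3"}]),
    ("g1 and (g2 or g3)", [{"g1", "g2"}, {"g1", "g3"}]),
    ("g1 and g2", [{"g1", "g2"}]),
    ("", []),
])
def test_gpr_conjuncts(rule, expected):
    assert [set(c) for c in gpr_conjuncts(rule)] == expected


_gene_names = st.sampled_from([f"g{i}" for i in range(6)])
_rules = st.recursive(
    _gene_names,
    lambda kids: st.tuples(st.sampled_from([" and ", " or "]),
                           st.lists(kids, min_size=2, max_size=3)).map(
        lambda t: "(" + t[0].join(t[1]) + ")"),
    max_leaves=8)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(rule=_rules, ko=st.sets(_gene_names, max_size=6))
def test_dnf_preserves_gpr_semantics(rule, ko):
    """The disjunctive normal form evaluates exactly like the original rule
    under every knockout set."""
    conjuncts = gpr_conjuncts(rule)
    dnf_active = any(not (set(c) & ko) for c in conjuncts)
    assert dnf_active == evaluate_gpr(rule, ko)


def test_expand_or_copies_reactions():
    model = build_model([
        ("EX_a", {"a_e": -1.0}, -10.0, 1000.0, ""),
        ("STEP", {"a_e": -1.0, "p_c": 1.0}, 0.0, 1000.0, "(g1 and g2) or g3"),
        ("PLAIN", {"p_c": -1.0, "q_c": 1.0}, 0.0, 1000.0, "g4"),
        ("BIOMASS", {"q_c": -1.0}, 0.0, 1000.0, ""),
    ], "BIOMASS")
    expanded, copy_of = expand_or_gprs(model)
    ids = {r.id for r in expanded.reactions}
    assert "STEP__iso2" in ids
    rules = {expanded.reactions.get_by_id("STEP").gene_reaction_rule,
             expanded.reactions.get_by_id("STEP__iso2").gene_reaction_rule}
    assert rules == {"g1 and g2", "g3"}
    assert copy_of["STEP__iso2"] == "STEP"
    # OR-free reactions untouched
    assert expanded.reactions.get_by_id("PLAIN").gene_reaction_rule == "g4"
    # feasible set unchanged: optimum identical
    assert slim_growth(expanded) == pytest.approx(slim_growth(model), abs=1e-6)


# --------------------------------------------------------------------------
# TRFBA
# --------------------------------------------------------------------------

def _capped_chain(expr=5.0, v_cap=8.0):
    """growth = min(E*c, v_cap): single gene-capped step + uptake cap."""
    return build_model([
        ("EX_a", {"a_e": -1.0}, -v_cap, 1000.0, ""),
        ("STEP", {"a_e": -1.0, "p_c": 1.0}, 0.0, 1000.0, "gj"),
        ("BIOMASS", {"p_c": -1.0}, 0.0, 1000.0, ""),
    ], "BIOMASS"), ExpressionProfile({"gj": expr}, "t")


def test_trfba_caps_single_reaction():
    model, _ = _capped_chain()
    profile = ExpressionProfile({"gj": 2.0}, "t")
    capped = apply_trfba(model, profile, c=3.0)
    assert slim_growth(capped) == pytest.approx(6.0, abs=1e-6)  # v <= E*c = 6
    with pytest.raises(ConfigError):
        apply_trfba(model, profile, c=-1.0)


def test_trfba_joint_bound_over_supported_set():
    model = build_model([
        ("EX_a", {"a_e": -1.0}, -100.0, 1000.0, ""),
        ("R1", {"a_e": -1.0, "p_c": 1.0}, 0.0, 1000.0, "gj"),
        ("R2", {"a_e": -1.0, "p_c": 1.0}, 0.0, 1000.0, "gj"),
        ("BIOMASS", {"p_c": -1.0}, 0.0, 1000.0, ""),
    ], "BIOMASS")
    profile = ExpressionProfile({"gj": 2.0}, "t")
    capped = apply_trfba(model, profile, c=3.0)
    # v_R1 + v_R2 <= 6 jointly, not 6 each
    assert slim_growth(capped) == pytest.approx(6.0, abs=1e-6)


def test_trfba_c_zero_closes_gene_supported_flux():
    model, profile = _capped_chain()
    assert slim_growth(apply_trfba(model, profile, c=0.0)) == pytest.approx(
        0.0, abs=1e-9)


def test_c_brk_closed_form_and_saturation():
    model, profile = _capped_chain(expr=5.0, v_cap=8.0)
    irrev, _ = convert_to_irreversible(model)
    c_brk = find_c_brk(irrev, profile)
    assert c_brk == pytest.approx(8.0 / 5.0, rel=2e-3)
    g1 = slim_growth(apply_trfba(model, profile, c_brk))
    g10 = slim_growth(apply_trfba(model, profile, 10 * c_brk))
    assert g1 == pytest.approx(g10, abs=1e-6)
    # growth non-decreasing on a grid of c values
    grid = [slim_growth(apply_trfba(model, profile, f * c_brk))
            for f in (0.1, 0.3, 0.5, 0.8, 1.0, 2.0)]
    assert all(a <= b + 1e-6 for a, b in zip(grid, grid[1:]))


def test_sweep_linear_regime_and_mapping(toy):
    model, profile = _capped_chain(expr=5.0, v_cap=8.0)
    sweep = stepwise_sweep(model, profile)
    assert len(sweep.points) == 9
    # growth = E*c below saturation: half C_brk gives half the plateau
    plateau = 8.0
    mid = sweep.points[4]  # c = 0.5 * c_brk
    assert mid.growth == pytest.approx(0.5 * plateau, rel=5e-3)
    assert sweep.points[-1].growth <= plateau + 1e-6
    # folded fluxes balance on the original model
    for point in sweep.points:
        if point.distribution.status == "optimal":
            assert_steady_state(model, point.distribution.fluxes)


def test_relaxation_chain_on_synthetic_panel(toy, toy_profiles, fitted_panel):
    """growth(GIMME+TRFBA at c) <= growth(GIMME model) <= growth(parent)."""
    model, truth = toy
    from fluxmark import apply_medium
    base = apply_medium(model, truth.medium)
    parent_growth = slim_growth(base)
    for profile, sweep in zip(toy_profiles, fitted_panel.sweeps):
        reduced = gimme_reduce(base, profile)
        reduced_growth = slim_growth(reduced)
        assert reduced_growth <= parent_growth + 1e-6
        growths = sweep.growths
        assert all(g <= reduced_growth + 1e-6 for g in growths)
        assert all(a <= b + 1e-6 for a, b in zip(growths, growths[1:]))


def test_sweep_distributions_balance_on_reduced_model(toy, toy_profiles):
    model, truth = toy
    from fluxmark import apply_medium
    base = apply_medium(model, truth.medium)
    reduced = gimme_reduce(base, toy_profiles[0])
    sweep = stepwise_sweep(reduced, toy_profiles[0])
    assert len(sweep.points) == 9
    for point in sweep.points:
        assert point.distribution.status == "optimal"
        assert_steady_state(reduced, point.distribution.fluxes)
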
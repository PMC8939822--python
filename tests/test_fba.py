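"""LP core: FBA, media, irreversible conversion, Manhattan norm,
precursor producibility."""

import numpy as np
import pytest

from fluxmark import (
    ConfigError,
    InfeasibleError,
    apply_medium,
    check_biomass_precursors,
    convert_to_irreversible,
    fba,
    minimize_manhattan_norm,
)
from fluxmark.fba import assert_steady_state, slim_growth

from .conftest import build_model
from .lp_oracle import oracle_fba_optimum


def _branched(variant):
    """Small branched networks (<= 8 reactions) for the enumeration oracle."""
    if variant == "split":
        return build_model([
            ("EX_a", {"a_e": -1.0}, -10.0, 1000.0, ""),
            ("R1", {"a_e": -1.0, "b_c": 1.0}, 0.0, 4.0, ""),
            ("R2", {"a_e": -1.0, "b_c": 0.5}, 0.0, 1000.0, ""),
            ("BIOMASS", {"b_c": -1.0}, 0.0, 1000.0, ""),
        ], "BIOMASS")
    if variant == "two_substrates":
        return build_model([
            ("EX_a", {"a_e": -1.0}, -6.0, 1000.0, ""),
            ("EX_b", {"b_e": -1.0}, -4.0, 1000.0, ""),
            ("RA", {"a_e": -1.0, "p_c": 1.0}, 0.0, 1000.0, ""),
            ("RB", {"b_e": -1.0, "p_c": 2.0}, 0.0, 3.0, ""),
            ("BIOMASS", {"p_c": -1.0}, 0.0, 1000.0, ""),
        ], "BIOMASS")
    if variant == "reversible_loop":
        return build_model([
            ("EX_a", {"a_e": -1.0}, -5.0, 1000.0, ""),
            ("T", {"a_e": -1.0, "a_c": 1.0}, -1000.0, 1000.0, ""),
            ("ISO", {"a_c": -1.0, "b_c": 1.0}, -1000.0, 1000.0, ""),
            ("BACK", {"b_c": -1.0, "a_c": 1.0}, 0.0, 1000.0, ""),
            ("BIOMASS", {"b_c": -1.0}, 0.0, 1000.0, ""),
        ], "BIOMASS")
    raise AssertionError(variant)


def test_single_path_optimum_is_uptake_bound(chain_model):
    sol = fba(chain_model)
    assert sol.status == "optimal"
    assert sol.objective_value == pytest.approx(10.0, abs=1e-6)
    assert_steady_state(chain_model, sol.fluxes)


def test_unproducible_precursor_gives_zero_growth():
    model = build_model([
        ("EX_a", {"a_e": -1.0}, -10.0, 1000.0, ""),
        ("T", {"a_e": -1.0, "a_c": 1.0}, 0.0, 1000.0, ""),
        ("BIOMASS", {"a_c": -1.0, "ghost_c": -1.0}, 0.0, 1000.0, ""),
    ], "BIOMASS")
    assert fba(model).objective_value == pytest.approx(0.0, abs=1e-6)
    status = check_biomass_precursors(model)
    assert status == {"a_c": "producible", "ghost_c": "dead_end"}


@pytest.mark.parametrize("variant", ["split", "two_substrates", "reversible_loop"])
def test_fba_matches_enumeration_oracle(variant):
    """The LP optimum equals the exhaustive basic-solution enumeration."""
    model = _branched(variant)
    expected = oracle_fba_optimum(model, "BIOMASS")
    got = fba(model).objective_value
    assert got == pytest.approx(expected, abs=1e-6)
    # and the irreversible conversion preserves the optimum
    irrev, _ = convert_to_irreversible(model)
    assert slim_growth(irrev) == pytest.approx(expected, abs=1e-6)


def test_apply_medium_contract(toy):
    model, truth = toy
    listed = dict(list(truth.medium.items())[:2])
    constrained = apply_medium(model, listed)
    for rid, lb in listed.items():
        assert constrained.reactions.get_by_id(rid).bounds == (lb, 1000.0)
    closed = [rid for rid in truth.medium if rid not in listed]
    for rid in closed:
        assert constrained.reactions.get_by_id(rid).bounds == (0.0, 1000.0)
    # empty medium: biomass needs uptake, so growth collapses
    assert slim_growth(apply_medium(model, {})) == pytest.approx(0.0, abs=1e-6)
    with pytest.raises(ConfigError):
        apply_medium(model, {"BIOMASS": -1.0})


def test_constraining_never_raises_optimum(toy):
    model, truth = toy
    parent = slim_growth(apply_medium(model, truth.medium))
    half = {rid: lb / 2 for rid, lb in truth.medium.items()}
    assert slim_growth(apply_medium(model, half)) <= parent + 1e-6


def test_irreversible_conversion_shape():
    model = _branched("reversible_loop")
    n_rev = sum(1 for r in model.reactions if r.lower_bound < 0)
    irrev, mapping = convert_to_irreversible(model)
    assert len(irrev.reactions) == len(model.reactions) + n_rev
    for rid, orig in mapping.backward_of.items():
        back = irrev.reactions.get_by_id(rid)
        fwd = irrev.reactions.get_by_id(orig)
        assert back.lower_bound == 0 and fwd.lower_bound == 0
        assert back.upper_bound == -model.reactions.get_by_id(orig).lower_bound
    # folded optimal fluxes still balance on the original model
    sol = fba(irrev)
    assert_steady_state(model, mapping.fold(sol.fluxes))


def test_manhattan_norm_prefers_short_route():
    """Two routes to biomass (1 vs 2 reactions): all flux takes the short one."""
    model = build_model([
        ("EX_a", {"a_e": -1.0}, -10.0, 1000.0, ""),
        ("SHORT", {"a_e": -1.0, "p_c": 1.0}, 0.0, 1000.0, ""),
        ("LONG1", {"a_e": -1.0, "m_c": 1.0}, 0.0, 1000.0, ""),
        ("LONG2", {"m_c": -1.0, "p_c": 1.0}, 0.0, 1000.0, ""),
        ("BIOMASS", {"p_c": -1.0}, 0.0, 1000.0, ""),
    ], "BIOMASS")
    growth = fba(model).objective_value
    dist = minimize_manhattan_norm(model, growth)
    assert dist.fluxes["SHORT"] == pytest.approx(growth, abs=1e-5)
    assert dist.fluxes["LONG1"] == pytest.approx(0.0, abs=1e-5)
    # oracle: enumerate the two pure route assignments
    norms = {"short": 3 * growth, "long": 4 * growth}
    total = sum(abs(v) for v in dist.fluxes.values())
    assert total == pytest.approx(min(norms.values()), abs=1e-4)
    # optimality vs plain FBA at the same growth
    plain = fba(model)
    assert total <= sum(abs(v) for v in plain.fluxes.values()) + 1e-6

    zero = minimize_manhattan_norm(model, 0.0)
    assert all(abs(v) <= 1e-5 for v in zero.fluxes.values())
    with pytest.raises(InfeasibleError):
        minimize_manhattan_norm(model, growth * 2)


def test_growing_model_has_all_precursors_producible(toy_open):
    status = check_biomass_precursors(toy_open)
    assert set(status.values()) == {"producible"}


def test_optimal_distributions_satisfy_steady_state(toy_open):
    sol = fba(toy_open)
    residual = assert_steady_state(toy_open, sol.fluxes)
    assert residual <= 1e-6
    lows = [v for v in sol.fluxes.values()]
    assert np.isfinite(lows).all()
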
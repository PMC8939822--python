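"""Flux balance analysis core.

Everything downstream (deletion screens, expression integration, biomarker
selection) consumes the two primitives defined here: an LP maximising the
flux of an objective reaction subject to the steady-state constraint
``S v = 0`` and flux bounds, and a secondary LP that fixes the achieved
growth rate and minimises the Manhattan norm ``sum_i |v_i|`` of the flux
vector to strip away degenerate futile flux.

Conventions follow BiGG/COBRA practice: fluxes in mmol gDCW^-1 h^-1,
"infinite" bounds encoded as +/-1000, exchange fluxes negative for uptake
and positive for secretion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import cobra
from optlang.symbolics import Zero

from .exceptions import ConfigError, InfeasibleError, SolverError
from .io import exchange_reactions, objective_reaction

#: feasibility / zero-flux tolerance used throughout the package
FLUX_TOL = 1e-6

EXCHANGE_UPPER_BOUND = 1000.0


@dataclass
class FluxDistribution:
    """One steady-state flux vector.

    ``objective_value`` is the flux of the objective reaction (the growth
    rate when the objective is biomass); ``status`` is the solver status
    (``optimal``, ``infeasible`` or ``unbounded``).
    """

    fluxes: dict[str, float] = field(default_factory=dict)
    objective_value: float = float("nan")
    status: str = "optimal"

    def __getitem__(self, rid: str) -> float:
        return self.fluxes[rid]


@dataclass(frozen=True)
class Medium:
    """Uptake bounds for exchange reactions (negative = uptake allowed)."""

    uptake_bounds: dict[str, float]


@dataclass(frozen=True)
class IrreversibleMapping:
    """Bookkeeping of the reversible -> irreversible split.

    ``forward_of[rid]`` / ``backward_of[rid]`` give the original reaction a
    split reaction came from; the net original flux is
    ``v[forward] - v[backward]``.
    """

    forward_of: dict[str, str]
    backward_of: dict[str, str]

    def fold(self, fluxes: dict[str, float]) -> dict[str, float]:
        """Map fluxes on the irreversible model back onto original ids."""
        net: dict[str, float] = {}
        for rid, v in fluxes.items():
            if rid in self.backward_of:
                orig = self.backward_of[rid]
                net[orig] = net.get(orig, 0.0) - v
            else:
                orig = self.forward_of.get(rid, rid)
                net[orig] = net.get(orig, 0.0) + v
        return net


def _medium_dict(medium) -> dict[str, float]:
    if isinstance(medium, Medium):
        return medium.uptake_bounds
    return dict(medium)


def apply_medium(model: cobra.Model, medium) -> cobra.Model:
    """Return a copy of ``model`` with the medium imposed.

    Exchanges named in the medium get the given lower bound; every other
    exchange has its uptake closed (lower bound 0); all exchange upper
    bounds are set to 1000 (free secretion).
    """
    bounds = _medium_dict(medium)
    model = model.copy()
    ex_ids = {r.id for r in exchange_reactions(model)}
    bad = sorted(set(bounds) - ex_ids)
    if bad:
        raise ConfigError(f"medium entries are not exchange reactions: {bad}")
    for rid in ex_ids:
        rxn = model.reactions.get_by_id(rid)
        rxn.bounds = (bounds.get(rid, 0.0), EXCHANGE_UPPER_BOUND)
    return model


def fba(model: cobra.Model, objective: str | None = None) -> FluxDistribution:
    """Maximise the flux of ``objective`` (default: the model objective)."""
    with model:
        if objective is not None:
            if objective not in model.reactions:
                raise ConfigError(f"objective reaction {objective!r} not in model")
            model.objective = objective
        obj_rxn = objective_reaction(model)
        solution = model.optimize()
        if solution.status != "optimal":
            return FluxDistribution(fluxes={}, objective_value=float("nan"),
                                    status=solution.status)
        return FluxDistribution(
            fluxes=dict(solution.fluxes),
            objective_value=float(solution.fluxes[obj_rxn.id]),
            status="optimal",
        )


def slim_growth(model: cobra.Model) -> float:
    """Maximal objective flux, nan -> 0.0 on infeasibility."""
    value = model.slim_optimize(error_value=float("nan"))
    return 0.0 if math.isnan(value) else float(value)


def convert_to_irreversible(model: cobra.Model) -> tuple[cobra.Model, IrreversibleMapping]:
    """Split every reversible reaction into forward/backward halves.

    A reaction with bounds ``[lb, ub]`` and ``lb < 0`` becomes a forward copy
    with bounds ``[0, max(ub, 0)]`` and a backward copy (negated
    stoichiometry, id suffixed ``__rev``) with bounds ``[0, -lb]``; GPR and
    subsystem are copied to both.  The feasible flux sets are equivalent, so
    any FBA optimum is preserved.
    """
    model = model.copy()
    forward_of, backward_of = {}, {}
    new_reactions = []
    for rxn in model.reactions:
        forward_of[rxn.id] = rxn.id
        if rxn.lower_bound < 0:
            back = cobra.Reaction(
                rxn.id + "__rev",
                name=(rxn.name or rxn.id) + " (backward)",
                lower_bound=0.0,
                upper_bound=-rxn.lower_bound,
            )
            back.subsystem = rxn.subsystem
            back.notes = dict(rxn.notes)
            new_reactions.append((back, rxn))
            backward_of[back.id] = rxn.id
            rxn.bounds = (0.0, max(rxn.upper_bound, 0.0))
    model.add_reactions([b for b, _ in new_reactions])
    for back, rxn in new_reactions:
        back.add_metabolites({m: -c for m, c in rxn.metabolites.items()})
        back.gene_reaction_rule = rxn.gene_reaction_rule
    return model, IrreversibleMapping(forward_of=forward_of, backward_of=backward_of)


def _manhattan_objective(model: cobra.Model, weights: dict[str, float] | None = None):
    """optlang expression for sum_i w_i |v_i| via forward+reverse variables."""
    expr = Zero
    for rxn in model.reactions:
        w = 1.0 if weights is None else weights.get(rxn.id, 0.0)
        if w:
            expr += w * (rxn.forward_variable + rxn.reverse_variable)
    return expr


def minimize_manhattan_norm(
    model: cobra.Model,
    required_growth: float,
    tol: float = FLUX_TOL,
) -> FluxDistribution:
    """Minimise ``sum_i |v_i|`` with the objective flux fixed at
    ``required_growth`` (within a ``tol`` band).

    Raises :class:`InfeasibleError` when that growth rate is infeasible.
    """
    obj_rxn = objective_reaction(model)
    with model:
        rxn = model.reactions.get_by_id(obj_rxn.id)
        rxn.bounds = (required_growth - tol, required_growth + tol)
        model.objective = model.problem.Objective(
            _manhattan_objective(model), direction="min")
        solution = model.optimize()
        if solution.status != "optimal":
            raise InfeasibleError(
                f"growth {required_growth} infeasible for Manhattan-norm step "
                f"(status {solution.status})"
            )
        return FluxDistribution(
            fluxes=dict(solution.fluxes),
            objective_value=float(solution.fluxes[obj_rxn.id]),
            status="optimal",
        )


def check_biomass_precursors(model: cobra.Model, tol: float = FLUX_TOL) -> dict[str, str]:
    """Producibility check of every biomass substrate.

    For each metabolite consumed by the biomass reaction a temporary demand
    reaction is added and its maximal flux computed; the precursor is
    ``producible`` when that maximum exceeds ``tol`` and ``dead_end``
    otherwise.  If the model grows, every precursor must be producible.
    """
    biomass = objective_reaction(model)
    result: dict[str, str] = {}
    for met, coeff in biomass.metabolites.items():
        if coeff >= 0:
            continue
        with model:
            demand = cobra.Reaction(f"__DM_probe_{met.id}",
                                    lower_bound=0.0, upper_bound=1000.0)
            model.add_reactions([demand])
            demand.add_metabolites({met: -1.0})
            model.objective = demand
            vmax = model.slim_optimize(error_value=0.0)
        result[met.id] = "producible" if vmax > tol else "dead_end"
    return result


def assert_steady_state(model: cobra.Model, fluxes: dict[str, float],
                        tol: float = FLUX_TOL) -> float:
    """Max |S v| residual of a flux vector over all metabolites; raises
    :class:`SolverError` when it exceeds ``tol``."""
    balance: dict[str, float] = {m.id: 0.0 for m in model.metabolites}
    for rid, v in fluxes.items():
        rxn = model.reactions.get_by_id(rid)
        for met, coeff in rxn.metabolites.items():
            balance[met.id] += coeff * v
    residual = max(abs(b) for b in balance.values()) if balance else 0.0
    if residual > tol:
        raise SolverError(f"steady-state residual {residual:.3g} exceeds {tol}")
    return residual
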
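"""Transcriptomics integration: GIMME reduction and TRFBA sweeps.

The pipeline builds one context-specific flux program per cell line in two
stages, mirroring how expression data is commonly layered onto a
genome-scale model:

1. **GIMME** removes reactions supported only by lowly expressed genes.
   Reaction-level expression is derived from the GPR (min over AND, max
   over OR); the low-expression threshold is a percentile (default 25th)
   of the profile's gene levels.  An LP minimises the expression-weighted
   inconsistency ``sum (threshold - expr_i) |v_i|`` over below-threshold
   reactions while forcing growth to stay at or above a fraction (default
   90%) of the maximum; below-threshold reactions carrying no flux in that
   solution are removed.

2. **TRFBA** caps, for every measured gene j, the summed flux of the
   reactions it supports: ``sum_{i in K_j} v_i <= E_j * C`` on a model made
   irreversible and OR-free (each top-level OR branch becomes its own
   reaction copy, so isozymes are capped independently).  ``C`` (flux per
   expression unit, mmol gDCW^-1 h^-1) is swept stepwise from 0 to the
   saturation point ``C_brk`` — the smallest C at which growth stops
   increasing — at 0.1 C_brk increments, yielding nine flux distributions
   per cell line.  Each point maximises growth and then minimises the
   Manhattan norm at that growth to suppress degeneracy; fluxes are mapped
   back to the original reaction ids (copies summed, directions
   differenced).
"""

from __future__ import annotations

import ast
import logging
import math
import warnings
from dataclasses import dataclass, field

import cobra
import numpy as np
from optlang.symbolics import Zero

from .exceptions import ConfigError, InfeasibleError, SearchError
from .fba import (
    FLUX_TOL,
    FluxDistribution,
    IrreversibleMapping,
    _manhattan_objective,
    convert_to_irreversible,
    slim_growth,
)
from .io import objective_reaction

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExpressionProfile:
    """Nonnegative expression levels per gene for one cell line."""

    levels: dict[str, float]
    cell_line: str = ""

    def __post_init__(self):
        bad = {g: v for g, v in self.levels.items() if v < 0 or math.isnan(v)}
        if bad:
            raise ConfigError(f"negative/NaN expression levels: {bad}")


@dataclass(frozen=True)
class IntegrationConfig:
    """Tunable parameters of the GIMME + TRFBA pipeline.

    ``gimme_percentile`` — percentile of the profile's gene levels used as
    the low-expression threshold (default 25, linear interpolation).
    ``growth_fraction`` — fraction of maximal growth GIMME must preserve
    (default 0.9).  ``sweep_steps`` — number of sweep points between 0 and
    C_brk, exclusive (default 9, i.e. 0.1..0.9 C_brk).  Genes present in
    the model but absent from a profile are treated as above threshold and
    left unconstrained when ``missing_genes_unconstrained`` (default).
    """

    gimme_percentile: float = 25.0
    growth_fraction: float = 0.9
    sweep_steps: int = 9
    or_expansion_cap: int = 32
    missing_genes_unconstrained: bool = True

    def __post_init__(self):
        if not 0 < self.growth_fraction <= 1:
            raise ConfigError("growth_fraction must be in (0, 1]")
        if not 0 <= self.gimme_percentile <= 100:
            raise ConfigError("gimme_percentile must be in [0, 100]")
        if self.sweep_steps < 1:
            raise ConfigError("sweep_steps must be >= 1")


@dataclass
class SweepPoint:
    c_value: float
    growth: float
    distribution: FluxDistribution


@dataclass
class SweepResult:
    """Per-cell-line output of the stepwise TRFBA scan."""

    cell_line: str
    c_brk: float
    points: list[SweepPoint] = field(default_factory=list)

    @property
    def growths(self) -> list[float]:
        return [p.growth for p in self.points]


# ---------------------------------------------------------------------------
# reaction-level expression and GIMME
# ---------------------------------------------------------------------------

def reaction_expression(rule, levels: dict[str, float]) -> float:
    """Expression of a reaction from its GPR: min over AND, max over OR.

    Genes missing from ``levels`` and empty rules map to +inf (no evidence
    against the reaction).
    """
    gpr = rule if not isinstance(rule, str) else cobra.core.gene.GPR.from_string(rule)
    if gpr.body is None:
        return math.inf

    def visit(node) -> float:
        if isinstance(node, ast.Name):
            return levels.get(node.id, math.inf)
        if isinstance(node, ast.BoolOp):
            vals = [visit(v) for v in node.values]
            return min(vals) if isinstance(node.op, ast.And) else max(vals)
        raise ConfigError(f"unsupported GPR node {node!r}")

    return visit(gpr.body)


def gimme_threshold(profile: ExpressionProfile, percentile: float = 25.0) -> float:
    """Low-expression cutoff: a percentile of the profile's gene levels
    (linear interpolation, so the 25th percentile of {1,2,3,4} is 1.75)."""
    if not profile.levels:
        raise ConfigError("expression profile is empty")
    return float(np.percentile(list(profile.levels.values()), percentile))


def gimme_reduce(
    model: cobra.Model,
    profile: ExpressionProfile,
    config: IntegrationConfig = IntegrationConfig(),
) -> cobra.Model:
    """Remove reactions supported only by low-expression genes while keeping
    at least ``growth_fraction`` of the maximal growth rate.

    Returns a reduced copy of ``model``; raises :class:`InfeasibleError`
    when no reduction satisfying the growth constraint exists.
    """
    obj_id = objective_reaction(model).id
    gmax = slim_growth(model)
    if gmax <= FLUX_TOL:
        raise ConfigError("GIMME requires wild-type growth > 0")
    threshold = gimme_threshold(profile, config.gimme_percentile)
    expr = {r.id: reaction_expression(r.gpr, profile.levels) for r in model.reactions}
    below = {rid: threshold - e for rid, e in expr.items()
             if e < threshold and rid != obj_id}
    if not below:
        return model.copy()

    irrev, mapping = convert_to_irreversible(model)
    weights = {}
    for rxn in irrev.reactions:
        orig = mapping.backward_of.get(rxn.id, rxn.id)
        if orig in below:
            weights[rxn.id] = below[orig]
    with irrev:
        irrev.reactions.get_by_id(obj_id).lower_bound = config.growth_fraction * gmax
        irrev.objective = irrev.problem.Objective(
            _manhattan_objective(irrev, weights), direction="min")
        solution = irrev.optimize()
        if solution.status != "optimal":
            raise InfeasibleError(
                f"GIMME inconsistency LP infeasible at growth fraction "
                f"{config.growth_fraction} (status {solution.status})")
        net = mapping.fold(dict(solution.fluxes))

    to_remove = [rid for rid in below if abs(net.get(rid, 0.0)) <= FLUX_TOL]
    reduced = model.copy()
    reduced.remove_reactions([reduced.reactions.get_by_id(r) for r in to_remove],
                             remove_orphans=True)
    reduced_gmax = slim_growth(reduced)
    if reduced_gmax + FLUX_TOL < config.growth_fraction * gmax:
        raise InfeasibleError(
            f"reduced model grows at {reduced_gmax:.6g} < "
            f"{config.growth_fraction} * {gmax:.6g}")
    logger.info("GIMME[%s]: threshold %.4g, removed %d/%d below-threshold reactions",
                profile.cell_line, threshold, len(to_remove), len(below))
    return reduced


# ---------------------------------------------------------------------------
# OR expansion (the "withoutOR" conversion)
# ---------------------------------------------------------------------------

def _dnf(node) -> list[frozenset[str]]:
    """Disjunctive normal form of a GPR ast: list of conjunct gene sets."""
    if isinstance(node, ast.Name):
        return [frozenset([node.id])]
    if isinstance(node, ast.BoolOp):
        if isinstance(node.op, ast.Or):
            out: list[frozenset[str]] = []
            for child in node.values:
                for conj in _dnf(child):
                    if conj not in out:
                        out.append(conj)
            return out
        # AND: cross product of children DNFs
        product: list[frozenset[str]] = [frozenset()]
        for child in node.values:
            product = [a | b for a in product for b in _dnf(child)]
        seen: list[frozenset[str]] = []
        for conj in product:
            if conj not in seen:
                seen.append(conj)
        return seen
    raise ConfigError(f"unsupported GPR node {node!r}")


def gpr_conjuncts(rule) -> list[frozenset[str]]:
    """Top-level OR branches of a GPR, each a conjunction of gene ids
    (after normalisation to disjunctive form).  Empty rule -> []."""
    gpr = rule if not isinstance(rule, str) else cobra.core.gene.GPR.from_string(rule)
    if gpr.body is None:
        return []
    return _dnf(gpr.body)


def expand_or_gprs(
    model: cobra.Model,
    cap: int = 32,
) -> tuple[cobra.Model, dict[str, str]]:
    """Replace every reaction whose GPR is an OR of k conjuncts by k parallel
    copies, one conjunct each (identical stoichiometry and bounds).

    Intended for irreversible models (the TRFBA precondition).  Returns the
    expanded model and a mapping copy id -> source reaction id.  Expansions
    beyond ``cap`` conjuncts are truncated with a warning.
    """
    model = model.copy()
    copy_of: dict[str, str] = {}
    additions: list[tuple[cobra.Reaction, cobra.Reaction, frozenset[str]]] = []
    for rxn in model.reactions:
        copy_of[rxn.id] = rxn.id
        conjuncts = gpr_conjuncts(rxn.gpr)
        if len(conjuncts) <= 1:
            if conjuncts:  # normalise to a plain conjunction
                rxn.gene_reaction_rule = " and ".join(sorted(conjuncts[0]))
            continue
        if len(conjuncts) > cap:
            warnings.warn(
                f"reaction {rxn.id}: GPR expands to {len(conjuncts)} conjuncts; "
                f"truncated to {cap}", stacklevel=2)
            conjuncts = conjuncts[:cap]
        rxn.gene_reaction_rule = " and ".join(sorted(conjuncts[0]))
        for k, conj in enumerate(conjuncts[1:], start=2):
            copy = cobra.Reaction(f"{rxn.id}__iso{k}", name=rxn.name,
                                  lower_bound=rxn.lower_bound,
                                  upper_bound=rxn.upper_bound)
            copy.subsystem = rxn.subsystem
            additions.append((copy, rxn, conj))
            copy_of[copy.id] = rxn.id
    model.add_reactions([c for c, _, _ in additions])
    for copy, rxn, conj in additions:
        copy.add_metabolites(dict(rxn.metabolites))
        copy.gene_reaction_rule = " and ".join(sorted(conj))
    return model, copy_of


def fold_fluxes(
    fluxes: dict[str, float],
    copy_of: dict[str, str] | None = None,
    mapping: IrreversibleMapping | None = None,
) -> dict[str, float]:
    """Map fluxes from the expanded model back to original reaction ids:
    OR copies are summed, then forward/backward splits differenced."""
    if copy_of is not None:
        summed: dict[str, float] = {}
        for rid, v in fluxes.items():
            src = copy_of.get(rid, rid)
            summed[src] = summed.get(src, 0.0) + v
        fluxes = summed
    if mapping is not None:
        fluxes = mapping.fold(fluxes)
    return fluxes


# ---------------------------------------------------------------------------
# TRFBA constraints
# ---------------------------------------------------------------------------

class TrfbaConstraints:
    """Expression-capacity constraints ``sum_{i in K_j} v_i <= E_j * C``
    attached to an irreversible, OR-free model, with an updatable C.

    K_j collects every reaction whose (conjunctive) GPR contains gene j;
    orphan reactions are unconstrained, as are genes missing from the
    profile when the config says so.
    """

    def __init__(self, model: cobra.Model, profile: ExpressionProfile,
                 config: IntegrationConfig = IntegrationConfig()):
        self.model = model
        self.profile = profile
        self._constraints = {}
        self._levels = {}
        supported: dict[str, list[cobra.Reaction]] = {}
        for rxn in model.reactions:
            conjuncts = gpr_conjuncts(rxn.gpr)
            if not conjuncts:
                continue
            if len(conjuncts) > 1:
                raise ConfigError(
                    f"reaction {rxn.id} still has OR branches; run expand_or_gprs first")
            for gid in conjuncts[0]:
                supported.setdefault(gid, []).append(rxn)
        constraints = []
        for gid, rxns in sorted(supported.items()):
            if gid not in profile.levels:
                if config.missing_genes_unconstrained:
                    continue
                level = 0.0
            else:
                level = profile.levels[gid]
            expr = Zero
            for rxn in rxns:
                expr += rxn.forward_variable
            cons = model.problem.Constraint(expr, ub=0.0, name=f"trfba_{gid}")
            constraints.append(cons)
            self._constraints[gid] = cons
            self._levels[gid] = level
        model.add_cons_vars(constraints)

    def set_c(self, c: float) -> None:
        if c < 0:
            raise ConfigError(f"TRFBA parameter C must be nonnegative, got {c}")
        for gid, cons in self._constraints.items():
            cons.ub = self._levels[gid] * c

    def remove(self) -> None:
        self.model.remove_cons_vars(list(self._constraints.values()))
        self._constraints.clear()


def apply_trfba(
    model: cobra.Model,
    profile: ExpressionProfile,
    c: float,
    config: IntegrationConfig = IntegrationConfig(),
) -> cobra.Model:
    """Return a copy of the (irreversible, OR-free) model with the TRFBA
    constraints at parameter ``c`` attached."""
    if c < 0:
        raise ConfigError(f"TRFBA parameter C must be nonnegative, got {c}")
    model = model.copy()
    TrfbaConstraints(model, profile, config).set_c(c)
    return model


# ---------------------------------------------------------------------------
# C_brk search and stepwise sweep
# ---------------------------------------------------------------------------

_C_MAX = 1e9


def _growth_at(constraints: TrfbaConstraints, c: float) -> float:
    constraints.set_c(c)
    return slim_growth(constraints.model)


def find_c_brk(
    model: cobra.Model,
    profile: ExpressionProfile,
    config: IntegrationConfig = IntegrationConfig(),
    rel_tol: float = 1e-3,
    growth_tol: float = FLUX_TOL,
) -> float:
    """Smallest C (within relative tolerance) at which TRFBA-constrained
    growth reaches the C-unconstrained maximum, by doubling then bisection.

    ``model`` must already be irreversible and OR-free.  Raises
    :class:`SearchError` when growth has not saturated by C = 1e9.
    """
    gmax = slim_growth(model)
    if gmax <= growth_tol:
        raise ConfigError("unconstrained growth must be > 0 to search for C_brk")
    constraints = TrfbaConstraints(model, profile, config)
    try:
        def saturated(c: float) -> bool:
            return _growth_at(constraints, c) >= gmax - growth_tol

        hi = 1.0
        if saturated(hi):
            lo = hi
            while lo > 1e-9 and saturated(lo / 2):
                lo /= 2
            if lo <= 1e-9:
                return lo
            lo, hi = lo / 2, lo
        else:
            while not saturated(hi):
                hi *= 2
                if hi > _C_MAX:
                    raise SearchError(
                        f"growth never saturates within C <= {_C_MAX:.0e}")
            lo = hi / 2
        while hi - lo > rel_tol * hi:
            mid = 0.5 * (lo + hi)
            if saturated(mid):
                hi = mid
            else:
                lo = mid
        return hi
    finally:
        constraints.remove()


@dataclass
class PreparedModel:
    """An irreversible, OR-free model with the transform bookkeeping needed
    to fold fluxes back onto the source model's reaction ids."""

    model: cobra.Model
    mapping: IrreversibleMapping
    copy_of: dict[str, str]

    def fold(self, fluxes: dict[str, float]) -> dict[str, float]:
        return fold_fluxes(fluxes, self.copy_of, self.mapping)


def prepare_for_trfba(model: cobra.Model,
                      cap: int = 32) -> PreparedModel:
    """Irreversible conversion followed by OR expansion."""
    irrev, mapping = convert_to_irreversible(model)
    expanded, copy_of = expand_or_gprs(irrev, cap=cap)
    return PreparedModel(model=expanded, mapping=mapping, copy_of=copy_of)


def stepwise_sweep(
    model: cobra.Model,
    profile: ExpressionProfile,
    config: IntegrationConfig = IntegrationConfig(),
) -> SweepResult:
    """Sweep C from 0 to C_brk in steps of C_brk/(steps+1) (nine interior
    points by default) and record one degeneracy-reduced flux distribution
    per point, on the original reaction ids.

    ``model`` is the (typically GIMME-reduced) source model in its original
    reversible form; the irreversible/OR-free transform is applied here.
    Infeasible points are recorded with their solver status and the sweep
    continues.
    """
    prepared = prepare_for_trfba(model, cap=config.or_expansion_cap)
    work = prepared.model
    obj_id = objective_reaction(work).id
    c_brk = find_c_brk(work, profile, config)
    constraints = TrfbaConstraints(work, profile, config)
    result = SweepResult(cell_line=profile.cell_line, c_brk=c_brk)
    try:
        for k in range(1, config.sweep_steps + 1):
            c = c_brk * k / (config.sweep_steps + 1)
            constraints.set_c(c)
            growth = work.slim_optimize(error_value=float("nan"))
            if math.isnan(growth):
                result.points.append(SweepPoint(
                    c_value=c, growth=float("nan"),
                    distribution=FluxDistribution(status="infeasible")))
                continue
            with work:
                work.reactions.get_by_id(obj_id).bounds = (
                    growth - FLUX_TOL, growth + FLUX_TOL)
                work.objective = work.problem.Objective(
                    _manhattan_objective(work), direction="min")
                solution = work.optimize()
                if solution.status != "optimal":
                    dist = FluxDistribution(status=solution.status)
                else:
                    dist = FluxDistribution(
                        fluxes=prepared.fold(dict(solution.fluxes)),
                        objective_value=float(solution.fluxes[obj_id]),
                        status="optimal")
            result.points.append(SweepPoint(c_value=c, growth=float(growth),
                                            distribution=dist))
    finally:
        constraints.remove()
    logger.info("sweep[%s]: C_brk %.5g, growths %s", profile.cell_line, c_brk,
                ["%.4g" % g for g in result.growths])
    return result
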
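"""Deterministic toy metabolic networks and cell-line expression programs.

The generator emulates, at desk scale, the structures the pipeline must
handle in a real genome-scale model: a compartmentalised stoichiometric
network with exchange and biomass pseudo-reactions, AND/OR gene-protein-
reaction rules (enzyme complexes and isozymes), orphan reactions, and
several cell lines whose expression programs emphasise different pathways.

Topology: ``n_linear_pathways`` parallel linear pathways each import a
dedicated nutrient through an exchange + transport step and convert it in
``pathway_length`` internal steps into one of ``biomass_precursors`` shared
precursor metabolites; the biomass pseudo-reaction drains one unit of each
precursor.  Pathway p feeds precursor ``min(p, n_precursors - 1)``, so the
first ``n_precursors - 1`` precursors have a single producing route (its
blocking genes are essential) and the last collects all remaining pathways
(alternative routes, the substrate for synthetic lethality, GIMME pruning
and line differentiation).

Every structural choice is drawn from one NumPy generator keyed by ``seed``,
so a spec regenerates byte-identically.  The ground truth (essential genes,
synthetic-lethal pairs, per-pathway reaction and gene sets) is derived from
the construction, independently of any LP, and is what the deletion screens
and PCA grouping are tested against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import cobra
import numpy as np

from .exceptions import ConfigError, GenerationError
from .fba import FLUX_TOL, apply_medium, slim_growth
from .integration import ExpressionProfile

#: internal compartments cycled through after the cytosol
_EXTRA_COMPARTMENTS = ["m", "r", "g", "l", "x", "n", "v", "e2"]

NUTRIENT_UPTAKE = 10.0  # mmol/gDCW/h allowed uptake per nutrient


@dataclass(frozen=True)
class ToyNetworkSpec:
    n_linear_pathways: int = 4
    pathway_length: int = 5
    n_isozyme_reactions: int = 2
    n_orphans: int = 1
    n_compartments: int = 2
    biomass_precursors: int = 2
    seed: int = 0

    def __post_init__(self):
        if min(self.n_linear_pathways, self.pathway_length,
               self.n_compartments, self.biomass_precursors) < 1:
            raise ConfigError("all toy-network counts must be >= 1 "
                              "(n_orphans may be 0)")
        if self.n_orphans < 0:
            raise ConfigError("n_orphans must be >= 0")
        if self.biomass_precursors > self.n_linear_pathways:
            raise ConfigError("need at least one pathway per biomass precursor")
        if self.n_compartments > len(_EXTRA_COMPARTMENTS) + 2:
            raise ConfigError("too many compartments requested")
        if self.n_linear_pathways > 10:
            raise ConfigError("at most 10 pathways (yields stay positive)")


@dataclass
class GroundTruth:
    """Construction-derived truth used to validate the analysis stages."""

    essential_genes: set[str]
    synthetic_lethal_pairs: set[frozenset[str]]
    pathway_reactions: dict[int, list[str]]
    pathway_genes: dict[int, set[str]]
    precursor_routes: dict[int, list[int]]
    medium: dict[str, float]
    gene_pathway: dict[str, int] = field(default_factory=dict)


def _compartment_cycle(spec: ToyNetworkSpec) -> list[str]:
    return ["c"] + _EXTRA_COMPARTMENTS[: spec.n_compartments - 2]


def _pathway_yield(p: int) -> float:
    """Final-step precursor yield of pathway p (distinct per pathway)."""
    return 1.0 - 0.05 * p


def generate_toy_network(spec: ToyNetworkSpec) -> tuple[cobra.Model, GroundTruth]:
    """Build the toy model and its ground truth; raises
    :class:`GenerationError` if the model cannot grow on its full medium."""
    rng = np.random.default_rng(spec.seed)
    P, L, K = spec.n_linear_pathways, spec.pathway_length, spec.biomass_precursors
    comps = _compartment_cycle(spec)

    model = cobra.Model(f"toy_P{P}_L{L}_seed{spec.seed}")
    model.compartments = {c: c for c in comps + ["e"]}
    mets: dict[str, cobra.Metabolite] = {}

    def met(mid: str, compartment: str) -> cobra.Metabolite:
        if mid not in mets:
            mets[mid] = cobra.Metabolite(mid, compartment=compartment)
            model.add_metabolites([mets[mid]])
        return mets[mid]

    # feature assignment over all internal steps, drawn from the seeded rng
    steps = [(p, s) for p in range(P) for s in range(1, L + 1)]
    order = [steps[i] for i in rng.permutation(len(steps))]
    n_iso = min(spec.n_isozyme_reactions, len(order))
    iso_steps = set(order[:n_iso])
    rest = order[n_iso:]
    n_orph = min(spec.n_orphans, len(rest))
    orphan_steps = set(rest[:n_orph])
    rest = rest[n_orph:]
    and_steps = set()
    for p in range(P):  # one enzyme-complex step per pathway where room allows
        for cand in rest:
            if cand[0] == p and cand not in and_steps:
                and_steps.add(cand)
                break

    truth = GroundTruth(
        essential_genes=set(), synthetic_lethal_pairs=set(),
        pathway_reactions={}, pathway_genes={}, precursor_routes={},
        medium={},
    )
    route_blockers: dict[int, set[str]] = {}
    route_iso_pairs: dict[int, list[frozenset[str]]] = {}

    precursor_of = {p: min(p, K - 1) for p in range(P)}
    for q in range(K):
        truth.precursor_routes[q] = [p for p in range(P) if precursor_of[p] == q]
    for q in range(K):
        met(f"prec{q}_c", "c")

    reactions: list[tuple[cobra.Reaction, dict, str]] = []

    def add_reaction(rid, stoich, gpr="", bounds=(0.0, 1000.0), pclass="none",
                     subsystem=""):
        rxn = cobra.Reaction(rid, lower_bound=bounds[0], upper_bound=bounds[1])
        rxn.notes["pseudo_class"] = pclass
        rxn.subsystem = subsystem
        reactions.append((rxn, stoich, gpr))
        return rxn

    for p in range(P):
        q = precursor_of[p]
        sub = f"pathway_{p}"
        blockers: set[str] = set()
        iso_pairs: list[frozenset[str]] = []
        genes_p: set[str] = set()
        rxn_ids: list[str] = []

        n_e = met(f"n{p}_e", "e")
        n_c = met(f"n{p}_c", "c")
        add_reaction(f"EX_n{p}", {n_e: -1.0}, bounds=(-NUTRIENT_UPTAKE, 1000.0),
                     pclass="exchange", subsystem="exchange")
        rxn_ids.append(f"EX_n{p}")
        tgene = f"gt{p}"
        add_reaction(f"T{p}", {n_e: -1.0, n_c: 1.0}, gpr=tgene, subsystem=sub)
        rxn_ids.append(f"T{p}")
        blockers.add(tgene)
        genes_p.add(tgene)

        substrate = n_c
        for s in range(1, L + 1):
            comp = comps[s % len(comps)]
            product = (met(f"prec{q}_c", "c") if s == L
                       else met(f"i{p}_{s}_{comp}", comp))
            rid = f"R{p}_{s}"
            # pathways have distinct final-step yields so the Manhattan-norm
            # LP has a unique (greedy) optimum over redundant routes and the
            # flux split reflects the expression caps instead of solver ties
            coeff = _pathway_yield(p) if s == L else 1.0
            if (p, s) in iso_steps:
                ga, gb = f"g{p}s{s}a", f"g{p}s{s}b"
                gpr = f"{ga} or {gb}"
                iso_pairs.append(frozenset((ga, gb)))
                genes_p |= {ga, gb}
            elif (p, s) in orphan_steps:
                gpr = ""
            elif (p, s) in and_steps:
                gx, gy = f"g{p}s{s}x", f"g{p}s{s}y"
                gpr = f"{gx} and {gy}"
                blockers |= {gx, gy}
                genes_p |= {gx, gy}
            else:
                g = f"g{p}s{s}"
                gpr = g
                blockers.add(g)
                genes_p.add(g)
            add_reaction(rid, {substrate: -1.0, product: coeff}, gpr=gpr,
                         subsystem=sub)
            rxn_ids.append(rid)
            substrate = product

        truth.medium[f"EX_n{p}"] = -NUTRIENT_UPTAKE
        truth.pathway_reactions[p] = rxn_ids
        truth.pathway_genes[p] = genes_p
        for g in genes_p:
            truth.gene_pathway[g] = p
        route_blockers[p] = blockers
        route_iso_pairs[p] = iso_pairs

    add_reaction("BIOMASS",
                 {met(f"prec{q}_c", "c"): -1.0 for q in range(K)},
                 bounds=(0.0, 1000.0), pclass="biomass", subsystem="biomass")

    model.add_reactions([r for r, _, _ in reactions])
    for rxn, stoich, gpr in reactions:
        rxn.add_metabolites(stoich)
        if gpr:
            rxn.gene_reaction_rule = gpr
    model.objective = "BIOMASS"

    # ground truth from the construction (no LP involved)
    for q, routes in truth.precursor_routes.items():
        if len(routes) == 1:
            # sole producing route: its blocking genes are essential and its
            # isozyme pairs jointly lethal
            p = routes[0]
            truth.essential_genes |= route_blockers[p]
            truth.synthetic_lethal_pairs |= set(route_iso_pairs[p])
        elif len(routes) == 2:
            # either route alone sustains the precursor, so no single blocker
            # is lethal but every cross-route blocker pair is
            p1, p2 = routes
            truth.synthetic_lethal_pairs |= {
                frozenset((x, y))
                for x in route_blockers[p1] for y in route_blockers[p2]}

    growth = slim_growth(apply_medium(model, truth.medium))
    if growth <= FLUX_TOL:
        raise GenerationError(
            f"generated model does not grow (growth={growth:.3g}); spec={spec}")
    return model, truth


@dataclass(frozen=True)
class ExpressionProgramSpec:
    """Cell-line expression programs over the toy pathways.

    ``programs`` maps, per line, pathway index -> activity multiplier; when
    ``None`` a default panel of ``n_lines`` programs is built in which line
    i up-weights pathway i (mod P) threefold.  Gene level = ``base_level`` x
    multiplier of the gene's pathway + Gaussian noise truncated at zero.
    """

    n_lines: int = 4
    programs: tuple[dict[int, float], ...] | None = None
    base_level: float = 100.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_lines < 1:
            raise ConfigError("need at least one cell line")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.programs is not None:
            if len(self.programs) != self.n_lines:
                raise ConfigError("one program per line required")
            for prog in self.programs:
                if any(m < 0 for m in prog.values()):
                    raise ConfigError("program multipliers must be >= 0")


SOLE_ROUTE_MULTIPLIER = 6.0


def default_programs(
    n_lines: int,
    n_pathways: int,
    redundant: list[int] | None = None,
    sole: list[int] | None = None,
) -> tuple[dict[int, float], ...]:
    """Distinct activity programs, one per line.

    Sole-route (housekeeping) pathways are expressed high in every line so
    the shared precursor fed by *redundant* routes stays rate-limiting
    during the TRFBA sweep — there each redundant route runs exactly at its
    expression cap, so the flux split is line-specific and non-degenerate.
    Lines then differ by which redundant route they up-weight (x1.5, one
    extra x0.5 per full cycle through the routes).  When the network has no
    redundancy all pathways are eligible for the up-weight.
    """
    targets = sorted(redundant) if redundant else list(range(n_pathways))
    R = len(targets)
    programs = []
    for i in range(n_lines):
        prog = {p: 1.0 for p in range(n_pathways)}
        for s in sole or []:
            prog[s] = SOLE_ROUTE_MULTIPLIER
        hi = targets[i % R]
        prog[hi] = 1.5 + 0.5 * (i // R)
        programs.append(prog)
    return tuple(programs)


def generate_expression_profiles(
    truth: GroundTruth,
    spec: ExpressionProgramSpec,
) -> list[ExpressionProfile]:
    """One profile per line over every gene of the generated network."""
    rng = np.random.default_rng(spec.seed)
    n_pathways = len(truth.pathway_genes)
    redundant = [p for routes in truth.precursor_routes.values()
                 if len(routes) > 1 for p in routes]
    sole = [routes[0] for routes in truth.precursor_routes.values()
            if len(routes) == 1]
    programs = spec.programs or default_programs(spec.n_lines, n_pathways,
                                                 redundant, sole)
    profiles = []
    for i, program in enumerate(programs):
        levels = {}
        for gid in sorted(truth.gene_pathway):
            mult = program.get(truth.gene_pathway[gid], 1.0)
            noise = rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0
            levels[gid] = max(0.0, spec.base_level * mult + noise)
        profiles.append(ExpressionProfile(levels=levels, cell_line=f"line{i}"))
    return profiles
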
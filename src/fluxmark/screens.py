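"""GPR-aware single and double gene-deletion screens.

A gene knockout disables every reaction whose gene-protein-reaction (GPR)
rule evaluates to false with the knocked-out genes set false (AND = enzyme
complex, OR = isozymes; an empty rule — an orphan reaction — is never
disabled).  The effect of a deletion is quantified by the GR ratio, the FBA
growth rate after deletion divided by the wild-type growth rate:

* ``lethal``   — GR ratio < 1e-5
* ``sick``     — GR ratio just below 1 (operationally < 1 - 1e-3)
* ``neutral``  — otherwise

The robustness summary normalises the screen the way model-comparison
tables do: growth-related single genes divided by the number of genes n,
growth-related pairs divided by n^2, and interacting genes (members of at
least one epistatic pair, GR(pair) < min of the single GRs minus tolerance)
divided by n.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from itertools import combinations

import cobra
import pandas as pd
from cobra.core.gene import GPR

from .exceptions import ConfigError, GPRParseError
from .fba import FLUX_TOL, apply_medium, slim_growth
from .io import objective_reaction

LETHAL_THRESHOLD = 1e-5
SICK_TOL = 1e-3


def evaluate_gpr(rule, knocked_out: set[str] | frozenset[str] = frozenset()) -> bool:
    """Evaluate a GPR rule with ``knocked_out`` genes false, all others true.

    ``rule`` may be a :class:`cobra.core.gene.GPR` or an infix rule string
    (``"(g1 and g2) or g3"``).  An empty rule is always active.
    """
    if isinstance(rule, str):
        text = rule
        import warnings as _warnings
        with _warnings.catch_warnings():
            _warnings.simplefilter("error", SyntaxWarning)
            try:
                rule = GPR.from_string(text)
            except (SyntaxError, SyntaxWarning, TypeError, ValueError) as exc:
                raise GPRParseError(
                    f"cannot parse GPR rule {text!r}: {exc}") from exc
        if rule.body is None and text.strip():
            raise GPRParseError(f"cannot parse GPR rule {text!r}")
    elif not isinstance(rule, GPR):
        raise GPRParseError(f"not a GPR rule: {rule!r}")
    return bool(rule.eval(knockouts=knocked_out))


def knockout_inactive_reactions(model: cobra.Model, genes: set[str]) -> list[str]:
    """Reaction ids disabled by knocking out ``genes`` (bounds untouched)."""
    candidates: set[cobra.Reaction] = set()
    for gid in genes:
        if gid in model.genes:
            candidates |= set(model.genes.get_by_id(gid).reactions)
    return sorted(r.id for r in candidates if not evaluate_gpr(r.gpr, set(genes)))


@dataclass
class DeletionScreenResult:
    """GR ratios and classification from single/double deletion screens."""

    wild_type_growth: float
    n_genes: int
    single: dict[str, float] = field(default_factory=dict)
    classification: dict[str, str] = field(default_factory=dict)
    double: dict[frozenset[str], float] = field(default_factory=dict)

    def singles_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "gene": list(self.single),
            "gr_ratio": [self.single[g] for g in self.single],
            "class": [self.classification[g] for g in self.single],
        })

    def doubles_frame(self) -> pd.DataFrame:
        rows = []
        for pair in sorted(self.double, key=sorted):
            gi, gj = sorted(pair)
            rows.append({"gene_i": gi, "gene_j": gj, "gr_ratio": self.double[pair]})
        return pd.DataFrame(rows, columns=["gene_i", "gene_j", "gr_ratio"])


@dataclass(frozen=True)
class RobustnessSummary:
    """Normalised robustness metrics (the model-comparison table layout).

    ``growth_related_ratio`` counts lethal + sick genes over n;
    ``growth_related_lethal_only_ratio`` reports the lethal-only variant
    since published tables do not state which is meant.
    """

    n_genes: int
    growth_related_ratio: float
    growth_related_lethal_only_ratio: float
    growth_related_double_ratio: float
    interaction_gene_ratio: float

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)


def _classify(ratio: float, lethal_threshold: float, sick_tol: float) -> str:
    if ratio < lethal_threshold:
        return "lethal"
    if ratio < 1.0 - sick_tol:
        return "sick"
    return "neutral"


def _prepare(model: cobra.Model, medium) -> cobra.Model:
    return apply_medium(model, medium) if medium is not None else model


def single_gene_deletion(
    model: cobra.Model,
    medium=None,
    lethal_threshold: float = LETHAL_THRESHOLD,
    sick_tol: float = SICK_TOL,
) -> DeletionScreenResult:
    """Knock out every gene one-by-one and record its GR ratio.

    Genes absent from every GPR, and knockouts that disable no reaction,
    get GR ratio 1 without an LP solve.
    """
    model = _prepare(model, medium)
    objective_reaction(model)
    wt = slim_growth(model)
    if wt <= FLUX_TOL:
        raise ConfigError(f"wild-type growth is {wt:.3g}; screen requires growth > 0")
    result = DeletionScreenResult(wild_type_growth=wt, n_genes=len(model.genes))
    for gene in model.genes:
        disabled = knockout_inactive_reactions(model, {gene.id})
        if not disabled:
            ratio = 1.0
        else:
            with model:
                for rid in disabled:
                    model.reactions.get_by_id(rid).bounds = (0.0, 0.0)
                ratio = max(slim_growth(model), 0.0) / wt
        result.single[gene.id] = ratio
        result.classification[gene.id] = _classify(ratio, lethal_threshold, sick_tol)
    return result


def double_gene_deletion(
    model: cobra.Model,
    medium=None,
    single: DeletionScreenResult | None = None,
    skip_lethal_singles: bool = True,
    lethal_threshold: float = LETHAL_THRESHOLD,
    sick_tol: float = SICK_TOL,
) -> DeletionScreenResult:
    """Knock out every unordered gene pair.

    Pairs containing a single-lethal gene inherit GR ratio 0 without
    re-solving when ``skip_lethal_singles`` (GR is monotone under additional
    deletions); pairs disabling no extra reaction beyond their singles'
    union keep the better-informed bound only when neither single hurt.
    """
    if single is None:
        single = single_gene_deletion(model, medium, lethal_threshold, sick_tol)
    model = _prepare(model, medium)
    wt = single.wild_type_growth
    result = DeletionScreenResult(
        wild_type_growth=wt, n_genes=single.n_genes,
        single=dict(single.single), classification=dict(single.classification))
    single_disabled = {g: knockout_inactive_reactions(model, {g})
                       for g in single.single}
    for gi, gj in combinations(sorted(single.single), 2):
        pair = frozenset((gi, gj))
        if skip_lethal_singles and (
            single.single[gi] < lethal_threshold or single.single[gj] < lethal_threshold
        ):
            result.double[pair] = 0.0
            continue
        disabled = knockout_inactive_reactions(model, {gi, gj})
        if not disabled:
            result.double[pair] = 1.0
            continue
        if disabled == single_disabled[gi] and not single_disabled[gj]:
            result.double[pair] = single.single[gi]
            continue
        if disabled == single_disabled[gj] and not single_disabled[gi]:
            result.double[pair] = single.single[gj]
            continue
        with model:
            for rid in disabled:
                model.reactions.get_by_id(rid).bounds = (0.0, 0.0)
            result.double[pair] = max(slim_growth(model), 0.0) / wt
    return result


def summarize_robustness(
    result: DeletionScreenResult,
    lethal_threshold: float = LETHAL_THRESHOLD,
    sick_tol: float = SICK_TOL,
    count_lethal_single_pairs: bool = False,
) -> RobustnessSummary:
    """Normalise the screen into comparable ratios.

    * growth-related genes: lethal + sick singles, over n (the lethal-only
      count is reported alongside);
    * growth-related pairs: pairs with GR < 1 - sick_tol whose effect is not
      already implied by a lethal single (include those too with
      ``count_lethal_single_pairs``), over n^2;
    * interacting genes: members of >=1 pair with
      GR(pair) < min(GR(i), GR(j)) - sick_tol, over n.
    """
    n = result.n_genes
    if n == 0:
        raise ConfigError("screen result contains no genes")
    lethal = {g for g, r in result.single.items() if r < lethal_threshold}
    affected = {g for g, r in result.single.items() if r < 1.0 - sick_tol}
    n_pairs_affected = 0
    interacting: set[str] = set()
    for pair, ratio in result.double.items():
        gi, gj = sorted(pair)
        if ratio < 1.0 - sick_tol:
            if count_lethal_single_pairs or (gi not in lethal and gj not in lethal):
                n_pairs_affected += 1
        if ratio < min(result.single[gi], result.single[gj]) - sick_tol:
            interacting |= {gi, gj}
    return RobustnessSummary(
        n_genes=n,
        growth_related_ratio=len(affected) / n,
        growth_related_lethal_only_ratio=len(lethal) / n,
        growth_related_double_ratio=n_pairs_affected / (n * n),
        interaction_gene_ratio=len(interacting) / n,
    )
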
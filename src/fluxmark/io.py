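"""Model input/output and descriptive statistics.

Two on-disk representations are supported:

* **SBML Level 3 + FBC** — read and written through cobrapy/libsbml; the
  interchange format genome-scale models are published in.
* **A plain tabular dialect** — a directory holding three TSV tables
  (``reactions.tsv``, ``metabolites.tsv``, ``genes.tsv``).  Stoichiometry is
  written as space-separated ``coeff met_id`` terms (e.g. ``-1 glc_c 1 g6p_c``)
  and GPR rules as infix boolean text with parentheses.  This mirrors the
  spreadsheet form models are often curated in, without a binary dependency;
  converting an XLSX workbook to these TSVs is a manual export step.

Reactions are classified into *pseudo* reactions (exchange, demand, sink,
biomass, ATP maintenance), *gene-associated* reactions (non-pseudo with a
non-empty GPR) and *orphan* reactions (non-pseudo, empty GPR).  When the file
does not tag pseudo reactions explicitly the BiGG id conventions are used:
``EX_``/``DM_``/``SK_`` prefixes, the declared objective, and an ``ATPM`` id.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import asdict, dataclass

import cobra
import pandas as pd
from cobra.util.solver import linear_reaction_coefficients

from .exceptions import ConfigError, StructureError

PSEUDO_CLASSES = ("none", "exchange", "demand", "sink", "biomass", "atp_maintenance")

_REACTION_COLUMNS = [
    "id", "name", "stoichiometry", "lower_bound", "upper_bound",
    "gpr", "subsystem", "pseudo_class",
]
_METABOLITE_COLUMNS = ["id", "name", "formula", "charge", "compartment"]


@dataclass(frozen=True)
class ModelStats:
    """Descriptive statistics of a metabolic model.

    The three reaction classes (gene-associated, orphan, pseudo) partition
    the reaction set: their counts always sum to ``n_reactions``.
    """

    n_reactions: int
    n_metabolites: int
    n_genes: int
    n_gene_associated: int
    n_orphan: int
    n_pseudo: int
    n_compartments: int
    n_subsystems: int
    gene_associated_ratio: float

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def objective_reaction(model: cobra.Model) -> cobra.Reaction:
    """Return the single reaction carrying the (linear) objective."""
    coeffs = linear_reaction_coefficients(model)
    if not coeffs:
        raise ConfigError("model declares no objective (biomass) reaction")
    if len(coeffs) > 1:
        raise ConfigError(
            f"model objective spans {len(coeffs)} reactions; exactly one expected"
        )
    return next(iter(coeffs))


def classify_pseudo(reaction: cobra.Reaction, objective_id: str | None = None) -> str:
    """Classify a reaction as one of :data:`PSEUDO_CLASSES`.

    An explicit ``pseudo_class`` entry in ``reaction.notes`` wins; otherwise
    BiGG id conventions are applied in the order exchange/demand/sink prefix,
    objective flag (biomass), ATPM id.
    """
    explicit = reaction.notes.get("pseudo_class")
    if explicit:
        if explicit not in PSEUDO_CLASSES:
            raise StructureError(
                f"reaction {reaction.id!r}: unknown pseudo_class {explicit!r}"
            )
        return explicit
    rid = reaction.id
    if rid.startswith("EX_"):
        return "exchange"
    if rid.startswith("DM_"):
        return "demand"
    if rid.startswith("SK_"):
        return "sink"
    if objective_id is not None and rid == objective_id:
        return "biomass"
    if rid.upper() == "ATPM":
        return "atp_maintenance"
    return "none"


def exchange_reactions(model: cobra.Model) -> list[cobra.Reaction]:
    """All reactions classified as exchanges."""
    return [r for r in model.reactions if classify_pseudo(r) == "exchange"]


def model_statistics(model: cobra.Model) -> ModelStats:
    """Count reactions, metabolites, genes, compartments and subsystems and
    partition the reactions into pseudo / gene-associated / orphan."""
    obj_id = objective_reaction(model).id
    n_pseudo = n_assoc = n_orphan = 0
    subsystems = set()
    for r in model.reactions:
        if classify_pseudo(r, obj_id) != "none":
            n_pseudo += 1
        elif r.gene_reaction_rule.strip():
            n_assoc += 1
        else:
            n_orphan += 1
        if r.subsystem and r.subsystem.strip():
            subsystems.add(r.subsystem.strip())
    compartments = {m.compartment for m in model.metabolites if m.compartment}
    n_rxn = len(model.reactions)
    return ModelStats(
        n_reactions=n_rxn,
        n_metabolites=len(model.metabolites),
        n_genes=len(model.genes),
        n_gene_associated=n_assoc,
        n_orphan=n_orphan,
        n_pseudo=n_pseudo,
        n_compartments=len(compartments),
        n_subsystems=len(subsystems),
        gene_associated_ratio=n_assoc / n_rxn if n_rxn else 0.0,
    )


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def read_model(path: str | os.PathLike, format: str = "sbml") -> cobra.Model:
    """Read a metabolic model from ``path``.

    Parameters
    ----------
    path
        SBML file, or the directory holding the three TSV tables of the
        tabular dialect.
    format
        ``"sbml"`` or ``"tabular"``.

    The returned model always has a declared objective whose reaction is the
    biomass pseudo-reaction; a file without one raises :class:`ConfigError`.
    """
    if format == "sbml":
        if not os.path.exists(path):
            raise FileNotFoundError(path)
        model = cobra.io.read_sbml_model(str(path))
        objective_reaction(model)  # must exist
        return model
    if format == "tabular":
        return _read_tabular(path)
    raise ConfigError(f"unknown model format {format!r}")


def _default_bounds(row) -> tuple[float, float]:
    lb, ub = row.get("lower_bound"), row.get("upper_bound")
    have_lb = lb is not None and not (isinstance(lb, float) and math.isnan(lb)) and str(lb) != ""
    have_ub = ub is not None and not (isinstance(ub, float) and math.isnan(ub)) and str(ub) != ""
    if have_lb and have_ub:
        return float(lb), float(ub)
    rev = row.get("reversible")
    irreversible = str(rev).strip() in {"0", "false", "False"} if rev is not None else False
    if irreversible:
        return (0.0, 1000.0)
    return (-1000.0, 1000.0)


def _parse_stoichiometry(text: str, rid: str) -> dict[str, float]:
    tokens = str(text).split()
    if len(tokens) % 2:
        raise StructureError(f"reaction {rid!r}: odd stoichiometry token count")
    stoich: dict[str, float] = {}
    for coeff, met in zip(tokens[::2], tokens[1::2]):
        try:
            stoich[met] = stoich.get(met, 0.0) + float(coeff)
        except ValueError as exc:
            raise StructureError(
                f"reaction {rid!r}: bad stoichiometric coefficient {coeff!r}"
            ) from exc
    return stoich


def _read_tsv(path: str, required: list[str]) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise StructureError(f"{path}: missing columns {missing}")
    return df


def _read_tabular(path: str | os.PathLike) -> cobra.Model:
    path = str(path)
    rxn_df = _read_tsv(os.path.join(path, "reactions.tsv"), ["id", "stoichiometry"])
    met_df = _read_tsv(os.path.join(path, "metabolites.tsv"), ["id", "compartment"])
    gene_df = _read_tsv(os.path.join(path, "genes.tsv"), ["id"])
    if len(rxn_df) == 0:
        raise StructureError("tabular model has an empty reaction table")

    model = cobra.Model(os.path.basename(os.path.normpath(path)) or "model")
    mets = {}
    for _, row in met_df.iterrows():
        met = cobra.Metabolite(
            row["id"],
            name=row.get("name", "") or row["id"],
            compartment=row["compartment"],
        )
        if row.get("formula"):
            met.formula = row["formula"]
        if row.get("charge"):
            met.charge = int(float(row["charge"]))
        mets[met.id] = met
    model.add_metabolites(list(mets.values()))
    model.compartments = {c: c for c in sorted({m.compartment for m in mets.values()})}

    declared_genes = set(gene_df["id"])
    biomass_id = None
    reactions = []
    for _, row in rxn_df.iterrows():
        rid = row["id"]
        rxn = cobra.Reaction(rid, name=row.get("name", "") or rid)
        rxn.bounds = _default_bounds(row)
        rxn.subsystem = row.get("subsystem", "") or ""
        pclass = row.get("pseudo_class", "") or "none"
        if pclass not in PSEUDO_CLASSES:
            raise StructureError(f"reaction {rid!r}: unknown pseudo_class {pclass!r}")
        rxn.notes["pseudo_class"] = pclass
        if pclass == "biomass":
            if biomass_id is not None:
                raise StructureError(
                    f"two biomass reactions declared: {biomass_id!r} and {rid!r}"
                )
            biomass_id = rid
        reactions.append((rxn, row))
    model.add_reactions([r for r, _ in reactions])
    for rxn, row in reactions:
        stoich = _parse_stoichiometry(row["stoichiometry"], rxn.id)
        unknown = [m for m in stoich if m not in mets]
        if unknown:
            raise StructureError(
                f"reaction {rxn.id!r} references unknown metabolite(s) {unknown}"
            )
        rxn.add_metabolites({mets[m]: c for m, c in stoich.items()})
        rule = (row.get("gpr", "") or "").strip()
        if rule:
            rxn.gene_reaction_rule = rule

    undeclared = sorted(g.id for g in model.genes if g.id not in declared_genes)
    if undeclared:
        raise StructureError(
            f"GPR rules reference gene(s) absent from genes.tsv: {undeclared}"
        )
    for gid in sorted(declared_genes):
        if gid not in model.genes:
            gene = cobra.Gene(gid)
            gene._model = model
            model.genes.append(gene)

    if biomass_id is None:
        raise ConfigError("tabular model declares no biomass reaction")
    model.objective = biomass_id
    return model


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_model(model: cobra.Model, path: str | os.PathLike, format: str = "sbml") -> None:
    """Write ``model`` to ``path`` in the given format.

    Round-trip guarantee: ``read_model(write_model(m))`` reproduces the model
    statistics and every GPR truth table (ordering may differ).
    """
    if len(model.reactions) == 0:
        raise StructureError("refusing to write a model with no reactions")
    if format == "sbml":
        cobra.io.write_sbml_model(model, str(path))
        return
    if format == "tabular":
        _write_tabular(model, path)
        return
    raise ConfigError(f"unknown model format {format!r}")


def _fmt(x: float) -> str:
    return f"{x:.10g}"


def _write_tabular(model: cobra.Model, path: str | os.PathLike) -> None:
    path = str(path)
    os.makedirs(path, exist_ok=True)
    obj_id = objective_reaction(model).id
    rxn_rows = []
    for r in model.reactions:
        stoich = " ".join(
            f"{_fmt(c)} {m.id}"
            for m, c in sorted(r.metabolites.items(), key=lambda mc: mc[0].id)
        )
        rxn_rows.append({
            "id": r.id,
            "name": r.name or "",
            "stoichiometry": stoich,
            "lower_bound": _fmt(r.lower_bound),
            "upper_bound": _fmt(r.upper_bound),
            "gpr": r.gene_reaction_rule,
            "subsystem": r.subsystem or "",
            "pseudo_class": classify_pseudo(r, obj_id),
        })
    pd.DataFrame(rxn_rows, columns=_REACTION_COLUMNS).to_csv(
        os.path.join(path, "reactions.tsv"), sep="\t", index=False)
    met_rows = [{
        "id": m.id,
        "name": m.name or "",
        "formula": m.formula or "",
        "charge": "" if m.charge is None else str(m.charge),
        "compartment": m.compartment or "",
    } for m in model.metabolites]
    pd.DataFrame(met_rows, columns=_METABOLITE_COLUMNS).to_csv(
        os.path.join(path, "metabolites.tsv"), sep="\t", index=False)
    pd.DataFrame({"id": [g.id for g in model.genes]}).to_csv(
        os.path.join(path, "genes.tsv"), sep="\t", index=False)


# ---------------------------------------------------------------------------
# auxiliary tables
# ---------------------------------------------------------------------------

def read_medium(path: str | os.PathLike) -> dict[str, float]:
    """Read a growth medium as a two-column TSV (exchange id, lower bound).

    A header row is optional; negative bounds mean uptake is allowed.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = list(df.columns)
    rows = list(df.itertuples(index=False))
    try:  # headerless file: the header row is itself data
        float(cols[1])
        rows = [tuple(cols)] + [tuple(r) for r in rows]
    except (ValueError, IndexError):
        pass
    medium = {}
    for row in rows:
        medium[str(row[0])] = float(row[1])
    return medium


def write_medium(medium: dict[str, float], path: str | os.PathLike) -> None:
    pd.DataFrame(
        {"reaction": list(medium), "lower_bound": [medium[k] for k in medium]}
    ).to_csv(path, sep="\t", index=False)


def read_expression_tsv(path: str | os.PathLike, cell_line: str | None = None):
    """Read a two-column TSV (gene id, level) into an ExpressionProfile."""
    from .integration import ExpressionProfile

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = list(df.columns)
    rows = list(df.itertuples(index=False))
    try:
        float(cols[1])
        rows = [tuple(cols)] + [tuple(r) for r in rows]
    except (ValueError, IndexError):
        pass
    levels = {str(r[0]): float(r[1]) for r in rows}
    name = cell_line or os.path.splitext(os.path.basename(str(path)))[0]
    return ExpressionProfile(levels=levels, cell_line=name)
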
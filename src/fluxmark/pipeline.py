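"""End-to-end orchestration and statsmodels-style entry points.

Two model objects front the library: :class:`GeneDeletionScreen` (model
robustness to single/double knockouts) and :class:`FluxBiomarkerAnalysis`
(GIMME + stepwise-TRFBA integration of several cell lines followed by
correlation/PCA biomarker extraction).  Each is constructed from data,
``fit()`` runs the computation and returns a results object carrying the
estimates and a ``summary()`` table; file output hangs off the results.

:func:`run_pipeline` drives everything from a :class:`PipelineConfig`
(typically a JSON file) and writes a run directory of artifacts plus a
machine-readable manifest — that is what the command-line interface wraps.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field

import cobra
import numpy as np
import pandas as pd

from . import __version__
from .biomarkers import (
    BiomarkerReport,
    CorrelationRecord,
    common_reactions,
    growth_correlated_reactions,
    pca_differentiate,
    selected_set,
)
from .exceptions import ConfigError
from .fba import apply_medium, fba
from .integration import (
    ExpressionProfile,
    IntegrationConfig,
    SweepResult,
    gimme_reduce,
    stepwise_sweep,
)
from .io import (
    model_statistics,
    read_expression_tsv,
    read_medium,
    read_model,
)
from .screens import (
    DeletionScreenResult,
    RobustnessSummary,
    double_gene_deletion,
    single_gene_deletion,
    summarize_robustness,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# deletion screen as a fitted model
# ---------------------------------------------------------------------------

class GeneDeletionScreen:
    """Robustness screen of a metabolic model under a medium.

    Parameters
    ----------
    model : cobra.Model
    medium : mapping exchange id -> lower bound, optional
    double : bool
        Also run the pairwise screen (quadratic in gene count).
    """

    def __init__(self, model: cobra.Model, medium=None, double: bool = True,
                 lethal_threshold: float = 1e-5, sick_tol: float = 1e-3,
                 skip_lethal_singles: bool = True):
        self.model = model
        self.medium = medium
        self.double = double
        self.lethal_threshold = lethal_threshold
        self.sick_tol = sick_tol
        self.skip_lethal_singles = skip_lethal_singles

    def fit(self) -> "GeneDeletionScreenResults":
        single = single_gene_deletion(
            self.model, self.medium, self.lethal_threshold, self.sick_tol)
        result = single
        if self.double:
            result = double_gene_deletion(
                self.model, self.medium, single=single,
                skip_lethal_singles=self.skip_lethal_singles,
                lethal_threshold=self.lethal_threshold, sick_tol=self.sick_tol)
        summary = summarize_robustness(result, self.lethal_threshold, self.sick_tol)
        return GeneDeletionScreenResults(self, result, summary)


class GeneDeletionScreenResults:
    """Fitted deletion screen: GR ratios, classes and normalised ratios."""

    def __init__(self, model: GeneDeletionScreen, screen: DeletionScreenResult,
                 robustness: RobustnessSummary):
        self.model = model
        self.screen = screen
        self.robustness = robustness

    def summary(self) -> str:
        s, r = self.screen, self.robustness
        counts = pd.Series(list(s.classification.values())).value_counts()
        lines = [
            "Gene deletion screen",
            "=" * 58,
            f"genes                          {s.n_genes}",
            f"wild-type growth               {s.wild_type_growth:.6g}",
            f"lethal / sick / neutral        {counts.get('lethal', 0)} / "
            f"{counts.get('sick', 0)} / {counts.get('neutral', 0)}",
            f"growth-related gene ratio      {r.growth_related_ratio:.4g}",
            f"  (lethal only)                {r.growth_related_lethal_only_ratio:.4g}",
        ]
        if s.double:
            lines += [
                f"pairs screened                 {len(s.double)}",
                f"growth-related pair ratio      {r.growth_related_double_ratio:.4g}",
                f"interacting gene ratio         {r.interaction_gene_ratio:.4g}",
            ]
        return "\n".join(lines)

    def to_dir(self, outdir: str | os.PathLike) -> None:
        os.makedirs(outdir, exist_ok=True)
        self.screen.singles_frame().to_csv(
            os.path.join(outdir, "single_deletions.tsv"), sep="\t", index=False)
        if self.screen.double:
            self.screen.doubles_frame().to_csv(
                os.path.join(outdir, "double_deletions.tsv"), sep="\t", index=False)
        self.robustness.to_json(os.path.join(outdir, "robustness_summary.json"))


# ---------------------------------------------------------------------------
# integration + biomarkers as a fitted model
# ---------------------------------------------------------------------------

class FluxBiomarkerAnalysis:
    """Context-specific flux programs and biomarker reactions for a panel
    of cell lines.

    For each expression profile the model is GIMME-reduced, swept through
    nine TRFBA constraint strengths up to the saturation point C_brk, and
    the growth-correlated reactions are selected; the PCA over the common
    selection differentiates the lines.
    """

    def __init__(self, model: cobra.Model, profiles: list[ExpressionProfile],
                 medium=None, config: IntegrationConfig | None = None,
                 r_min: float = 0.9, p_max: float = 0.05,
                 use_abs_correlation: bool = False,
                 top_loading_quantile: float = 0.75,
                 pca_normalize: str | None = "growth"):
        if not profiles:
            raise ConfigError("at least one expression profile is required")
        names = [p.cell_line for p in profiles]
        if len(set(names)) != len(names):
            raise ConfigError(f"duplicate cell line labels: {names}")
        self.model = model
        self.profiles = profiles
        self.medium = medium
        self.config = config or IntegrationConfig()
        self.r_min = r_min
        self.p_max = p_max
        self.use_abs_correlation = use_abs_correlation
        self.top_loading_quantile = top_loading_quantile
        self.pca_normalize = pca_normalize

    @classmethod
    def from_files(cls, model_path, profile_paths: dict[str, str],
                   model_format: str = "sbml", medium_path=None, **kwargs):
        model = read_model(model_path, model_format)
        medium = read_medium(medium_path) if medium_path else None
        profiles = [read_expression_tsv(path, cell_line=line)
                    for line, path in profile_paths.items()]
        return cls(model, profiles, medium=medium, **kwargs)

    def fit(self) -> "FluxBiomarkerResults":
        base = apply_medium(self.model, self.medium) if self.medium is not None \
            else self.model
        sweeps: list[SweepResult] = []
        correlations: dict[str, list[CorrelationRecord]] = {}
        per_line: dict[str, set[str]] = {}
        for profile in self.profiles:
            t0 = time.perf_counter()
            reduced = gimme_reduce(base, profile, self.config)
            sweep = stepwise_sweep(reduced, profile, self.config)
            sweeps.append(sweep)
            records = growth_correlated_reactions(
                sweep, self.r_min, self.p_max, self.use_abs_correlation)
            correlations[profile.cell_line] = records
            per_line[profile.cell_line] = selected_set(records)
            logger.info("line %s: %d/%d reactions growth-correlated (%.2fs)",
                        profile.cell_line, len(per_line[profile.cell_line]),
                        len(records), time.perf_counter() - t0)
        common = common_reactions(per_line)
        report = None
        if common:
            report = pca_differentiate(
                sweeps, common, per_line_selected=per_line,
                top_loading_quantile=self.top_loading_quantile,
                normalize=self.pca_normalize)
        return FluxBiomarkerResults(self, sweeps, correlations, per_line,
                                    sorted(common), report)


class FluxBiomarkerResults:
    """Fitted panel: per-line sweeps, correlation records and PCA report."""

    def __init__(self, model: FluxBiomarkerAnalysis, sweeps: list[SweepResult],
                 correlations: dict[str, list[CorrelationRecord]],
                 per_line_selected: dict[str, set[str]],
                 common: list[str], report: BiomarkerReport | None):
        self.model = model
        self.sweeps = sweeps
        self.correlations = correlations
        self.per_line_selected = per_line_selected
        self.common_reactions = common
        self.report = report

    @property
    def n_distributions(self) -> int:
        return sum(len(s.points) for s in self.sweeps)

    def sweep_frame(self) -> pd.DataFrame:
        """Long-format (cell_line, c, reaction, flux) table of all sweeps."""
        rows = []
        for sweep in self.sweeps:
            for point in sweep.points:
                for rid, v in sorted(point.distribution.fluxes.items()):
                    rows.append((sweep.cell_line, point.c_value, rid, v))
        return pd.DataFrame(rows, columns=["cell_line", "c", "reaction", "flux"])

    def summary(self) -> str:
        lines = [
            "Flux biomarker analysis",
            "=" * 66,
            f"cell lines                  {len(self.sweeps)}",
            f"sweep points per line       "
            f"{[len(s.points) for s in self.sweeps]}",
            f"flux distributions          {self.n_distributions}",
            "",
            f"{'line':<10}{'C_brk':>12}{'max growth':>14}{'selected':>10}",
            "-" * 46,
        ]
        for sweep in self.sweeps:
            growths = [g for g in sweep.growths if not np.isnan(g)]
            lines.append(
                f"{sweep.cell_line:<10}{sweep.c_brk:>12.5g}"
                f"{(max(growths) if growths else float('nan')):>14.6g}"
                f"{len(self.per_line_selected[sweep.cell_line]):>10}")
        lines += ["", f"common growth-correlated reactions: "
                      f"{len(self.common_reactions)}"]
        if self.report is not None:
            vf = self.report.variance_fractions
            lines.append(
                "variance explained: " + ", ".join(
                    f"PC{i+1} {100 * f:.1f}%" for i, f in enumerate(vf[:4])))
            lines.append(
                f"top PC1 reactions: {', '.join(self.report.top_reactions[1][:6])}")
        return "\n".join(lines)

    def to_dir(self, outdir: str | os.PathLike) -> None:
        os.makedirs(outdir, exist_ok=True)
        self.sweep_frame().to_csv(os.path.join(outdir, "sweeps.tsv"),
                                  sep="\t", index=False)
        meta = {
            s.cell_line: {"c_brk": s.c_brk, "growths": s.growths}
            for s in self.sweeps
        }
        with open(os.path.join(outdir, "sweep_meta.json"), "w") as fh:
            json.dump(meta, fh, indent=2)
        corr_rows = []
        for line, records in self.correlations.items():
            for rec in records:
                corr_rows.append((line, rec.reaction, rec.r, rec.p, rec.selected))
        pd.DataFrame(corr_rows, columns=["cell_line", "reaction", "r", "p",
                                         "selected"]).to_csv(
            os.path.join(outdir, "correlations.tsv"), sep="\t", index=False)
        if self.report is not None:
            self.report.scores_frame().to_csv(
                os.path.join(outdir, "pca_scores.tsv"), sep="\t", index=False)
            self.report.loadings_frame().to_csv(
                os.path.join(outdir, "pca_loadings.tsv"), sep="\t")
            with open(os.path.join(outdir, "biomarkers.json"), "w") as fh:
                json.dump({
                    "common_reactions": self.common_reactions,
                    "variance_fractions":
                        [float(f) for f in self.report.variance_fractions],
                    "top_reactions":
                        {str(k): v for k, v in self.report.top_reactions.items()},
                }, fh, indent=2)


# ---------------------------------------------------------------------------
# pipeline configuration and runner
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Declarative description of one full run (usually loaded from JSON)."""

    model_path: str
    profile_paths: dict[str, str]
    outdir: str
    model_format: str = "sbml"
    medium_path: str | None = None
    run_screens: bool = True
    skip_double_deletion: bool = False
    lethal_threshold: float = 1e-5
    sick_tol: float = 1e-3
    r_min: float = 0.9
    p_max: float = 0.05
    seed: int = 0
    integration: IntegrationConfig = field(default_factory=IntegrationConfig)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        integ = IntegrationConfig(**raw.pop("integration", {}))
        try:
            return cls(integration=integ, **raw)
        except TypeError as exc:
            raise ConfigError(f"bad pipeline config {path}: {exc}") from exc

    def validate(self) -> None:
        if not os.path.exists(self.model_path):
            raise ConfigError(f"model path {self.model_path!r} does not exist")
        if self.medium_path and not os.path.exists(self.medium_path):
            raise ConfigError(f"medium path {self.medium_path!r} does not exist")
        for line, path in self.profile_paths.items():
            if not os.path.exists(path):
                raise ConfigError(
                    f"profile path for {line!r} ({path!r}) does not exist")
        if not 0 < self.lethal_threshold < 1:
            raise ConfigError("lethal_threshold must be in (0, 1)")
        if not 0 < self.r_min < 1 or not 0 < self.p_max <= 1:
            raise ConfigError("r_min must be in (0,1), p_max in (0,1]")

    def digest(self) -> str:
        payload = asdict(self)
        payload.pop("outdir", None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()


def run_pipeline(config: PipelineConfig) -> str:
    """Execute stats -> screens -> integration -> biomarkers; returns the
    run directory.  Each stage logs its timing; artifacts are plain TSV/JSON.
    """
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    np.random.seed(config.seed % (2**31))
    manifest: dict = {
        "package": "fluxmark",
        "version": __version__,
        "config_hash": config.digest(),
        "seed": config.seed,
        "stages": {},
    }

    def stage(name):
        t0 = time.perf_counter()
        logger.info("stage %s: start", name)
        return lambda extra=None: manifest["stages"].__setitem__(
            name, {"seconds": round(time.perf_counter() - t0, 3),
                   **(extra or {})})

    done = stage("load")
    model = read_model(config.model_path, config.model_format)
    medium = read_medium(config.medium_path) if config.medium_path else None
    profiles = [read_expression_tsv(path, cell_line=line)
                for line, path in sorted(config.profile_paths.items())]
    done({"reactions": len(model.reactions), "genes": len(model.genes)})

    done = stage("stats")
    stats = model_statistics(model)
    stats.to_json(os.path.join(config.outdir, "model_stats.json"))
    done()

    base = apply_medium(model, medium) if medium is not None else model
    growth = fba(base).objective_value
    manifest["wild_type_growth"] = growth

    if config.run_screens:
        done = stage("screens")
        results = GeneDeletionScreen(
            model, medium, double=not config.skip_double_deletion,
            lethal_threshold=config.lethal_threshold,
            sick_tol=config.sick_tol).fit()
        results.to_dir(config.outdir)
        done({"n_genes": results.screen.n_genes,
              "growth_related_ratio": results.robustness.growth_related_ratio})

    done = stage("integration")
    analysis = FluxBiomarkerAnalysis(
        model, profiles, medium=medium, config=config.integration,
        r_min=config.r_min, p_max=config.p_max)
    fitted = analysis.fit()
    fitted.to_dir(config.outdir)
    done({"cell_lines": len(profiles),
          "sweep_points": [len(s.points) for s in fitted.sweeps],
          "flux_distributions": fitted.n_distributions,
          "common_reactions": len(fitted.common_reactions)})

    with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    with open(os.path.join(config.outdir, "summary.txt"), "w") as fh:
        fh.write(fitted.summary() + "\n")
    return config.outdir
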
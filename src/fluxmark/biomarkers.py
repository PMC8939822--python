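"""Growth-correlated reaction selection and PCA differentiation.

For each cell line the stepwise sweep provides a growth series and one flux
series per reaction.  Reactions whose Pearson correlation with growth
exceeds ``r_min`` (default 0.9, signed) at ``p <= p_max`` (default 0.05,
two-sided t-test with n-2 df) are *growth-correlated*; the candidate
biomarker set is the intersection of those selections across cell lines.
A PCA over the (cell line x sweep point) observations restricted to the
common reactions then shows whether the flux programs separate the lines,
and the top-loading reactions per component are the reported biomarkers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .exceptions import ConfigError
from .integration import SweepResult

R_MIN = 0.9
P_MAX = 0.05


@dataclass(frozen=True)
class CorrelationRecord:
    """Pearson correlation of one reaction's flux series with growth."""

    reaction: str
    r: float
    p: float
    selected: bool


def _flux_matrix(sweep: SweepResult) -> tuple[list[str], np.ndarray, np.ndarray]:
    """(reaction ids, points x reactions flux matrix, growth vector) over the
    sweep's feasible points; reactions missing from a point count as 0."""
    points = [p for p in sweep.points if p.distribution.status == "optimal"]
    if len(points) < 3:
        raise ConfigError(
            f"sweep for {sweep.cell_line!r} has {len(points)} usable points; "
            "need at least 3 for correlation")
    rids = sorted({rid for p in points for rid in p.distribution.fluxes})
    X = np.array([[p.distribution.fluxes.get(rid, 0.0) for rid in rids]
                  for p in points])
    growth = np.array([p.growth for p in points])
    return rids, X, growth


def growth_correlated_reactions(
    sweep: SweepResult,
    r_min: float = R_MIN,
    p_max: float = P_MAX,
    use_abs: bool = False,
) -> list[CorrelationRecord]:
    """Correlate every reaction's flux series with the growth series.

    Constant series (zero variance, r undefined) are excluded.  With
    ``use_abs`` the threshold applies to |r| instead of signed r.
    """
    rids, X, growth = _flux_matrix(sweep)
    if np.ptp(growth) < 1e-12:
        raise ConfigError(
            f"growth series for {sweep.cell_line!r} is constant; "
            "correlation is undefined")
    records = []
    for j, rid in enumerate(rids):
        series = X[:, j]
        if np.ptp(series) < 1e-12:
            records.append(CorrelationRecord(rid, float("nan"), float("nan"), False))
            continue
        r, p = stats.pearsonr(series, growth)
        stat = abs(r) if use_abs else r
        records.append(CorrelationRecord(rid, float(r), float(p),
                                         bool(stat > r_min and p <= p_max)))
    return records


def selected_set(records: list[CorrelationRecord]) -> set[str]:
    return {rec.reaction for rec in records if rec.selected}


def common_reactions(per_line: dict[str, set[str]]) -> set[str]:
    """Intersection of the per-line growth-correlated reaction sets."""
    if not per_line:
        raise ConfigError("no cell lines supplied")
    sets = list(per_line.values())
    common = set(sets[0]).intersection(*sets[1:])
    if not common:
        warnings.warn("no reaction is growth-correlated in every cell line",
                      stacklevel=2)
    return common


@dataclass
class BiomarkerReport:
    """PCA over the selected flux dimensions plus the selections themselves.

    ``scores`` is (observations x components), ``loadings``
    (reactions x components); ``variance_fractions`` are non-increasing and
    sum to 1.  ``row_labels`` gives the cell line of each observation row.
    """

    per_line_selected: dict[str, set[str]]
    common_reactions: list[str]
    scores: np.ndarray
    loadings: np.ndarray
    variance_fractions: np.ndarray
    top_reactions: dict[int, list[str]]
    row_labels: list[str]
    column_means: np.ndarray = field(default=None)

    def scores_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.scores,
                          columns=[f"PC{i+1}" for i in range(self.scores.shape[1])])
        df.insert(0, "cell_line", self.row_labels)
        return df

    def loadings_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.loadings, index=self.common_reactions,
                          columns=[f"PC{i+1}" for i in range(self.loadings.shape[1])])
        df.index.name = "reaction"
        return df


def pca_differentiate(
    sweeps: list[SweepResult],
    reactions: set[str] | list[str],
    per_line_selected: dict[str, set[str]] | None = None,
    top_loading_quantile: float = 0.75,
    normalize: str | None = "growth",
) -> BiomarkerReport:
    """PCA of the sweep observations restricted to ``reactions``.

    Rows are the feasible sweep points of every cell line, columns the
    selected reactions, mean-centred per reaction (no variance scaling:
    all columns share flux units).  With ``normalize="growth"`` (default)
    each observation is divided by its growth rate, so rows are flux
    programs per unit growth and the sweep's common growth axis does not
    dominate the between-line differences; ``normalize=None`` uses raw
    fluxes.  Component signs are fixed so the largest-magnitude loading of
    each component is positive.  ``top_reactions`` ranks reactions by
    |loading| per component, cut at the given quantile of the component's
    absolute loadings.
    """
    if normalize not in (None, "growth"):
        raise ConfigError(f"unknown normalize mode {normalize!r}")
    rids = sorted(reactions)
    if not rids:
        raise ConfigError("no reactions selected for PCA")
    rows, labels = [], []
    for sweep in sweeps:
        for point in sweep.points:
            if point.distribution.status != "optimal":
                continue
            row = [point.distribution.fluxes.get(rid, 0.0) for rid in rids]
            if normalize == "growth":
                if not point.growth or abs(point.growth) < 1e-12:
                    continue  # zero-growth point has no flux program
                row = [v / point.growth for v in row]
            rows.append(row)
            labels.append(sweep.cell_line)
    if len(rows) < 2:
        raise ConfigError(f"{len(rows)} observations; PCA needs at least 2")
    X = np.asarray(rows, dtype=float)
    n_comp = min(X.shape)
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T  # reactions x components
    # deterministic sign: largest |loading| positive per component
    for k in range(loadings.shape[1]):
        j = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    top: dict[int, list[str]] = {}
    for k in range(loadings.shape[1]):
        mags = np.abs(loadings[:, k])
        cutoff = np.quantile(mags, top_loading_quantile)
        ranked = sorted(
            (rid for j, rid in enumerate(rids) if mags[j] >= cutoff),
            key=lambda rid: -mags[rids.index(rid)])
        top[k + 1] = ranked
    return BiomarkerReport(
        per_line_selected=per_line_selected or {},
        common_reactions=rids,
        scores=scores,
        loadings=loadings,
        variance_fractions=pca.explained_variance_ratio_.copy(),
        top_reactions=top,
        row_labels=labels,
        column_means=pca.mean_.copy(),
    )
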
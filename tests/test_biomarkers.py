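"""Correlation selection, intersection, PCA differentiation."""

import numpy as np
import pytest

from fluxmark import common_reactions, growth_correlated_reactions, pca_differentiate
from fluxmark.exceptions import ConfigError
from fluxmark.fba import FluxDistribution
from fluxmark.integration import SweepPoint, SweepResult


def make_sweep(cell_line, growths, flux_series):
    """SweepResult from a growth vector and {reaction: series} mapping."""
    points = []
    for i, g in enumerate(growths):
        fluxes = {rid: series[i] for rid, series in flux_series.items()}
        points.append(SweepPoint(
            c_value=0.1 * (i + 1), growth=float(g),
            distribution=FluxDistribution(fluxes=fluxes, objective_value=float(g))))
    return SweepResult(cell_line=cell_line, c_brk=1.0, points=points)


@pytest.fixture
def simple_sweep():
    g = np.arange(1.0, 10.0)
    return make_sweep("line", g, {
        "proportional": 2.0 * g,
        "anti": -g,
        "flat": np.full(9, 3.0),
        "noisy": g + np.array([0.3, -0.2, 0.1, -0.3, 0.2, -0.1, 0.3, -0.2, 0.1]),
    })


def test_correlation_selection_rules(simple_sweep):
    records = {r.reaction: r for r in growth_correlated_reactions(simple_sweep)}
    assert records["proportional"].r == pytest.approx(1.0)
    assert records["proportional"].selected
    assert records["anti"].r == pytest.approx(-1.0)
    assert not records["anti"].selected        # signed threshold
    assert not records["flat"].selected        # constant series excluded
    assert np.isnan(records["flat"].r)
    abs_records = {r.reaction: r for r in
                   growth_correlated_reactions(simple_sweep, use_abs=True)}
    assert abs_records["anti"].selected


def test_selection_invariant_to_growth_rescaling(simple_sweep):
    scaled = make_sweep("line", 7.5 * np.arange(1.0, 10.0), {
        rid: np.array([p.distribution.fluxes[rid] for p in simple_sweep.points])
        for rid in simple_sweep.points[0].distribution.fluxes})
    a = {(r.reaction, r.selected) for r in growth_correlated_reactions(simple_sweep)}
    b = {(r.reaction, r.selected) for r in growth_correlated_reactions(scaled)}
    assert a == b


def test_correlation_requires_three_points():
    sweep = make_sweep("x", [1.0, 2.0], {"r": np.array([1.0, 2.0])})
    with pytest.raises(ConfigError):
        growth_correlated_reactions(sweep)


def test_common_reactions_set_algebra():
    assert common_reactions({"a": {"A", "B", "C"}, "b": {"B", "C", "D"}}) == {"B", "C"}
    assert common_reactions({"a": {"A"}, "b": {"A"}}) == {"A"}
    with pytest.warns(UserWarning):
        assert common_reactions({"a": {"A"}, "b": {"B"}}) == set()


def _four_group_sweeps():
    """4 lines x 9 points; within a line all (growth-normalised) rows equal."""
    rng = np.random.default_rng(7)
    base = {f"line{i}": rng.uniform(0.5, 2.0, size=5) for i in range(4)}
    sweeps = []
    for line, shares in base.items():
        g = np.arange(1.0, 10.0)
        series = {f"R{j}": shares[j] * g for j in range(5)}
        sweeps.append(make_sweep(line, g, series))
    return sweeps


def test_pca_separates_identical_within_group_rows():
    sweeps = _four_group_sweeps()
    report = pca_differentiate(sweeps, {f"R{j}" for j in range(5)})
    # growth-normalised rows coincide within each line: within-group scores
    # identical, so between-group structure explains all variance
    assert report.variance_fractions.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.all(np.diff(report.variance_fractions) <= 1e-12)
    scores = report.scores
    for line in {"line0", "line1", "line2", "line3"}:
        rows = scores[[i for i, l in enumerate(report.row_labels) if l == line]]
        assert np.allclose(rows, rows[0], atol=1e-8)
    # 4 distinct groups span at most 3 centred dimensions
    assert np.all(report.variance_fractions[3:] < 1e-9)


def test_pca_reconstruction_and_sign_convention():
    sweeps = _four_group_sweeps()
    rids = sorted(f"R{j}" for j in range(5))
    report = pca_differentiate(sweeps, rids, normalize=None)
    X = np.array([[p.distribution.fluxes[rid] for rid in rids]
                  for s in sweeps for p in s.points])
    reconstructed = report.scores @ report.loadings.T + report.column_means
    assert np.allclose(reconstructed, X, atol=1e-8)
    for k in range(report.loadings.shape[1]):
        col = report.loadings[:, k]
        if np.max(np.abs(col)) > 1e-12:
            assert col[np.argmax(np.abs(col))] > 0


def test_pca_determinism(fitted_panel):
    """Re-running PCA on the same sweeps reproduces scores exactly."""
    rep1 = pca_differentiate(fitted_panel.sweeps, fitted_panel.common_reactions)
    rep2 = pca_differentiate(fitted_panel.sweeps, fitted_panel.common_reactions)
    assert np.array_equal(rep1.scores, rep2.scores)
    assert np.array_equal(rep1.loadings, rep2.loadings)
    assert rep1.top_reactions == rep2.top_reactions


def test_panel_pca_recovers_line_labels(fitted_panel):
    """PCA grouping of the synthetic panel matches the generating labels."""
    from sklearn.metrics import silhouette_score
    report = fitted_panel.report
    assert report is not None
    assert len(report.row_labels) == 36
    sil = silhouette_score(report.scores, report.row_labels)
    assert sil > 0.5
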
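"""Edge-corrected pcf estimation, the change statistic and its bands."""

import numpy as np
import pytest

from understory.data import RectWindow
from understory.pointpattern import (
    DeltaPCFCurve,
    DeltaPCFSummary,
    classify_interactions,
    default_r_grid,
    delta_pcf,
    isotropic_edge_weight,
    pcf_estimate,
    replicate_band,
    stoyan_bandwidth,
    _pcf_from_points,
)

from conftest import make_plot


def numeric_circle_fraction_weight(px, py, r, width, height, m=400_000):
    """Independent oracle: arc-sample the circle and count points inside."""
    theta = 2 * np.pi * (np.arange(m) + 0.5) / m
    x = px + r * np.cos(theta)
    y = py + r * np.sin(theta)
    frac = np.mean((x >= 0) & (x <= width) & (y >= 0) & (y <= height))
    return 1.0 / frac


# ---------------------------------------------------------------------------
# Edge weights


def test_edge_weight_interior_edge_and_corner():
    w = RectWindow(1.0, 1.0)
    assert isotropic_edge_weight(0.5, 0.5, 0.1, w) == pytest.approx(1.0)
    assert isotropic_edge_weight(0.0, 0.5, 0.05, w) == pytest.approx(2.0)
    assert isotropic_edge_weight(0.0, 0.0, 0.05, w) == pytest.approx(4.0)


def test_edge_weight_matches_numeric_integration_on_lattice():
    """Closed form vs arc integration over a 5 x 5 x 8 point/radius lattice."""
    win = RectWindow(1.1, 0.9)
    xs = np.linspace(0.0, 1.1, 5)
    ys = np.linspace(0.0, 0.9, 5)
    radii = [0.01, 0.03, 0.05, 0.1, 0.15, 0.2, 0.3, 0.45]
    worst = 0.0
    for px in xs:
        for py in ys:
            for r in radii:
                cf = isotropic_edge_weight(px, py, r, win)
                nm = numeric_circle_fraction_weight(px, py, r, 1.1, 0.9)
                worst = max(worst, abs(cf - nm))
    assert worst < 1e-5


def test_edge_weight_rejects_outside_points_and_bad_radius():
    w = RectWindow(1.0, 1.0)
    with pytest.raises(ValueError):
        isotropic_edge_weight(1.5, 0.5, 0.1, w)
    with pytest.raises(ValueError):
        isotropic_edge_weight(0.5, 0.5, 0.0, w)


def test_edge_weight_is_at_least_one_everywhere(rng):
    w = RectWindow(1.1, 0.9)
    px = rng.uniform(0, 1.1, 500)
    py = rng.uniform(0, 0.9, 500)
    r = rng.uniform(0.001, 0.44, 500)
    weights = isotropic_edge_weight(px, py, r, w)
    assert np.all(weights >= 1.0 - 1e-12)
    interior = (px > r) & (px < 1.1 - r) & (py > r) & (py < 0.9 - r)
    assert np.allclose(weights[interior], 1.0)


# ---------------------------------------------------------------------------
# pcf estimation


def csr_points(n, rng, width=1.1, height=0.9):
    return np.column_stack([rng.uniform(0, width, n), rng.uniform(0, height, n)])


def test_pcf_unbiased_under_csr(rng):
    win = RectWindow(1.1, 0.9)
    grid = np.linspace(0.02, 0.2, 19)
    h = stoyan_bandwidth(300 / win.area)
    means = np.mean(
        [
            _pcf_from_points(csr_points(rng.poisson(300), rng), win, grid, h, "isotropic").g_values
            for _ in range(60)
        ],
        axis=0,
    )
    assert means.min() > 0.93 and means.max() < 1.07


def test_uncorrected_pcf_is_biased_low_near_the_border(rng):
    """Both edge corrections remove the border bias that the uncorrected
    estimator shows under CSR; isotropic and translation agree."""
    win = RectWindow(1.1, 0.9)
    grid = np.array([0.15, 0.2])
    h = stoyan_bandwidth(300 / win.area)
    iso, trans, none = [], [], []
    for _ in range(40):
        pts = csr_points(rng.poisson(300), rng)
        iso.append(_pcf_from_points(pts, win, grid, h, "isotropic").g_values)
        trans.append(_pcf_from_points(pts, win, grid, h, "translation").g_values)
        none.append(_pcf_from_points(pts, win, grid, h, "none").g_values)
    assert np.mean(none, axis=0).max() < 0.9  # border loss uncorrected
    assert abs(np.mean(iso, axis=0) - 1).max() < 0.07
    assert abs(np.mean(trans, axis=0) - 1).max() < 0.07
    assert np.max(np.abs(np.mean(iso, axis=0) - np.mean(trans, axis=0))) < 0.05


def test_pcf_detects_clustering(rng):
    win = RectWindow(1.1, 0.9)
    grid = np.array([0.02, 0.2])
    gs = []
    for _ in range(40):
        parents = csr_points(30, rng)
        idx = rng.integers(0, 30, 300)
        pts = parents[idx] + rng.normal(0, 0.03, (300, 2))
        keep = (pts[:, 0] >= 0) & (pts[:, 0] <= 1.1) & (pts[:, 1] >= 0) & (pts[:, 1] <= 0.9)
        pts = pts[keep]
        gs.append(_pcf_from_points(pts, win, grid, stoyan_bandwidth(len(pts) / win.area),
                                   "isotropic").g_values)
    m = np.mean(gs, axis=0)
    assert m[0] > 1.5 > m[1]


def test_pcf_vanishes_below_hard_core_distance(rng):
    win = RectWindow(1.1, 0.9)
    pts = []
    while len(pts) < 150:
        cand = [rng.uniform(0, 1.1), rng.uniform(0, 0.9)]
        if all((cand[0] - p[0]) ** 2 + (cand[1] - p[1]) ** 2 >= 0.05**2 for p in pts):
            pts.append(cand)
    est = _pcf_from_points(np.array(pts), win, np.array([0.02, 0.03, 0.15]), 0.01, "isotropic")
    assert est.g_values[0] == pytest.approx(0.0, abs=1e-9)
    assert est.g_values[1] == pytest.approx(0.0, abs=1e-9)
    assert est.g_values[2] > 0.5


def test_pcf_requires_two_points_and_positive_radii():
    plot = make_plot([("A", 0.5, 0.5)])
    with pytest.raises(ValueError):
        pcf_estimate(plot)
    two = make_plot([("A", 0.5, 0.5), ("B", 0.6, 0.6)])
    with pytest.raises(ValueError):
        pcf_estimate(two, r_grid=np.array([-0.1, 0.1]), bandwidth=0.02)


def test_pcf_is_species_blind(rng):
    pts = csr_points(200, rng)
    labels_a = ["A"] * 200
    labels_b = ["A"] * 100 + ["B"] * 100
    grid = np.linspace(0.02, 0.2, 5)
    pa = make_plot([(s, x, y) for s, (x, y) in zip(labels_a, pts)])
    pb = make_plot([(s, x, y) for s, (x, y) in zip(labels_b, pts)])
    ga = pcf_estimate(pa, r_grid=grid, bandwidth=0.01)
    gb = pcf_estimate(pb, r_grid=grid, bandwidth=0.01)
    assert np.array_equal(ga.g_values, gb.g_values)


# ---------------------------------------------------------------------------
# delta pcf and bands


def test_identical_censuses_give_zero_change(rng):
    pts = csr_points(150, rng)
    t1 = make_plot([("A", x, y) for x, y in pts], census="t1")
    t2 = make_plot([("A", x, y) for x, y in pts], census="t2")
    curve = delta_pcf(t1, t2)
    assert np.allclose(curve.delta, 0.0)


def test_independent_thinning_leaves_pcf_unchanged_in_mean(rng):
    """The change statistic is centred on zero under scale-free mortality."""
    win = RectWindow(1.1, 0.9)
    grid = np.linspace(0.02, 0.2, 10)
    deltas = []
    for _ in range(60):
        pts = csr_points(400, rng)
        keep = rng.random(400) < 0.6
        t1 = make_plot([("A", x, y) for x, y in pts], census="t1")
        t2 = make_plot([("A", x, y) for x, y in pts[keep]], census="t2")
        deltas.append(delta_pcf(t1, t2, r_grid=grid).delta)
    mean = np.mean(deltas, axis=0)
    se = np.std(deltas, axis=0, ddof=1) / np.sqrt(len(deltas))
    assert np.all(np.abs(mean) < 4 * se + 0.02)


def test_replicate_band_matches_t_interval_formula():
    grid = np.array([0.05, 0.1])
    curves = [
        DeltaPCFCurve("p1", grid, np.array([0.1, -0.2]), 0.01, 10, 10),
        DeltaPCFCurve("p2", grid, np.array([0.3, -0.1]), 0.01, 10, 10),
        DeltaPCFCurve("p3", grid, np.array([0.2, -0.3]), 0.01, 10, 10),
    ]
    s = replicate_band(curves, band_type="t_ci_95")
    t975_df2 = 4.302652729911275  # Student t table value
    mean = np.array([0.2, -0.2])
    se = np.array([0.1, 0.1]) / np.sqrt(3)
    assert np.allclose(s.mean_delta, mean, atol=1e-12)
    assert np.allclose(s.ci_low, mean - t975_df2 * se, atol=1e-12)
    assert np.allclose(s.ci_high, mean + t975_df2 * se, atol=1e-12)
    sd_band = replicate_band(curves, band_type="mean_pm_1sd")
    assert np.allclose(sd_band.ci_high - sd_band.mean_delta, [0.1, 0.1], atol=1e-12)


def test_two_identical_curves_give_zero_width_band():
    grid = np.array([0.05, 0.1])
    c = DeltaPCFCurve("p", grid, np.array([0.4, -0.4]), 0.01, 5, 5)
    s = replicate_band([c, DeltaPCFCurve("q", grid, c.delta.copy(), 0.01, 5, 5)])
    assert np.allclose(s.ci_low, s.mean_delta)
    assert np.allclose(s.ci_high, s.mean_delta)


def test_band_requires_matching_grids():
    a = DeltaPCFCurve("p", np.array([0.05, 0.1]), np.zeros(2), 0.01, 5, 5)
    b = DeltaPCFCurve("q", np.array([0.06, 0.1]), np.zeros(2), 0.01, 5, 5)
    with pytest.raises(ValueError):
        replicate_band([a, b])


def _summary(mean, half):
    mean = np.asarray(mean, float)
    half = np.asarray(half, float)
    return DeltaPCFSummary(np.linspace(0.01, 0.2, mean.size), mean,
                           mean - half, mean + half, 12, "t_ci_95")


def test_sign_rule_classification():
    s = _summary([0.5, -0.5, 0.1], [0.2, 0.2, 0.5])
    assert list(classify_interactions(s)) == ["positive", "negative", "none"]


def test_classification_is_monotone_in_band_width():
    mean = np.array([0.3, -0.4, 0.05, -0.02])
    narrow = classify_interactions(_summary(mean, 0.1 * np.ones(4)))
    wide = classify_interactions(_summary(mean, 0.5 * np.ones(4)))
    for a, b in zip(narrow, wide):
        assert b == "none" or b == a  # widening only moves labels toward none
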
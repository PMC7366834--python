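"""Pair-correlation analysis of mapped plots, and the change statistic.

The pair correlation function g(r) is the expected density of further
individuals at distance r from a typical individual, standardised by the
mean intensity, so g = 1 under complete spatial randomness (CSR), g < 1
indicates inhibition and g > 1 clustering. It is estimated here with the
standard kernel estimator on a rectangular window,

    g_hat(r) = sum_{i != j} e_i(d_ij) k_h(r - d_ij) / (2 pi r lambda2 |W|),

where d_ij are pairwise distances, k_h is the Epanechnikov kernel with
bandwidth h (Stoyan's rule h = 0.15 / sqrt(lambda_hat) by default),
lambda2 = n(n-1)/|W|^2 is the unbiased pair-intensity estimate, and e_i is
Ripley's isotropic edge correction: the reciprocal fraction of the circle
of radius d_ij centred on point i that lies inside the window. Because the
estimator is a ratio of densities it is invariant, in expectation, to
independent thinning — the property that makes the *change*

    delta_g(r) = g_t2(r) - g_t1(r)

a detector of biotic interactions rather than of mere density loss:
distance-dependent mortality (competition between close neighbours)
depresses g at small r, while scale-free mortality leaves g unchanged at
every r. Replicate plots of a treatment provide a pointwise confidence band
for the mean delta_g, and the sign rule classifies each distance: the whole
band below zero reads as a negative interaction (competition), entirely
above as positive (facilitation), otherwise no call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.stats
from scipy.spatial.distance import cdist

from .data import CensusedPlot, Experiment, RectWindow

logger = logging.getLogger(__name__)

CORRECTIONS = ("isotropic", "translation", "none")
BAND_TYPES = ("t_ci_95", "mean_pm_1sd")

#: Ripley weights are capped here; on a rectangle the isotropic weight never
#: exceeds 4 (the corner quarter-circle) while r <= min(width, height).
MAX_EDGE_WEIGHT = 4.0


def _ripley_weight_raw(px, py, r, width: float, height: float):
    """Closed-form isotropic edge weight on a rectangle, vectorised.

    The circle of radius r centred at (px, py) is intersected with the four
    half-planes bounding the window. The arc beyond each edge at distance d
    has angular half-width arccos(min(d/r, 1)); arcs beyond two adjacent
    edges overlap by max(0, w_a + w_b - pi/2) (the corner case). Opposite
    edges can never both exclude the same arc point, so inclusion–exclusion
    over the four edges and four corners is exact for every r > 0.
    """
    px = np.asarray(px, dtype=float)
    py = np.asarray(py, dtype=float)
    r = np.asarray(r, dtype=float)
    with np.errstate(invalid="ignore"):
        wl = np.arccos(np.minimum(px / r, 1.0))
        wr = np.arccos(np.minimum((width - px) / r, 1.0))
        wb = np.arccos(np.minimum(py / r, 1.0))
        wt = np.arccos(np.minimum((height - py) / r, 1.0))
    outside = 2.0 * (wl + wr + wb + wt)
    for wa, wb_ in ((wl, wb), (wl, wt), (wr, wb), (wr, wt)):
        outside = outside - np.maximum(0.0, wa + wb_ - 0.5 * np.pi)
    frac = 1.0 - outside / (2.0 * np.pi)
    with np.errstate(divide="ignore"):
        return np.where(frac > 0, 1.0 / frac, np.inf)


def isotropic_edge_weight(px, py, r, window: RectWindow):
    """Ripley's isotropic edge-correction weight (>= 1) for a rectangle.

    1 / (fraction of the circumference of the circle of radius ``r`` centred
    at ``(px, py)`` lying inside ``window``); 1 for a fully interior circle,
    2 at an edge midpoint for small r, 4 at a corner.
    """
    px_a, py_a, r_a = np.broadcast_arrays(
        np.asarray(px, float), np.asarray(py, float), np.asarray(r, float)
    )
    if np.any(r_a <= 0):
        raise ValueError("radius must be positive")
    inside = (px_a >= 0) & (px_a <= window.width) & (py_a >= 0) & (py_a <= window.height)
    if not np.all(inside):
        raise ValueError("point(s) outside the window")
    w = _ripley_weight_raw(px_a, py_a, r_a, window.width, window.height)
    if w.ndim == 0:
        return float(w)
    return w


def stoyan_bandwidth(intensity: float) -> float:
    """Stoyan's rule-of-thumb pcf bandwidth h = 0.15 / sqrt(lambda)."""
    if intensity <= 0:
        raise ValueError("intensity must be positive")
    return 0.15 / np.sqrt(intensity)


def default_r_grid(window: RectWindow, bandwidth: float, n_points: int = 101) -> np.ndarray:
    """Default evaluation grid: ``n_points`` radii from h to min(W, H)/4.

    g_hat is not evaluated below the bandwidth, where the 1/r factor makes
    the kernel estimator unstable.
    """
    r_max = min(window.width, window.height) / 4.0
    lo = min(bandwidth, r_max / 2.0)
    return np.linspace(lo, r_max, n_points)


@dataclass(frozen=True)
class PCFEstimate:
    r_grid: np.ndarray
    g_values: np.ndarray
    n_points: int
    window: RectWindow
    bandwidth: float
    correction: str
    n_pairs_used: int
    n_pairs_excluded: int  # beyond the closed-form validity range


def _pcf_from_points(
    points: np.ndarray,
    window: RectWindow,
    r_grid: np.ndarray,
    bandwidth: float,
    correction: str,
) -> PCFEstimate:
    n = len(points)
    area = window.area
    lambda2 = n * (n - 1) / area**2
    r_grid = np.asarray(r_grid, dtype=float)
    if np.any(r_grid <= 0):
        raise ValueError("r grid entries must be positive")
    h = float(bandwidth)
    r_reach = float(r_grid.max()) + h

    d = cdist(points, points)
    np.fill_diagonal(d, np.inf)
    ii, jj = np.nonzero(d <= r_reach)
    dv = d[ii, jj]

    half_diag = 0.5 * float(np.hypot(window.width, window.height))
    excluded = int(np.sum(dv > half_diag))
    keep = dv <= half_diag
    ii, jj, dv = ii[keep], jj[keep], dv[keep]
    if excluded:
        logger.info("pcf: excluded %d pair(s) with distance beyond half the window diagonal", excluded)

    if correction == "isotropic":
        w = _ripley_weight_raw(points[ii, 0], points[ii, 1], dv, window.width, window.height)
        w = np.minimum(w, MAX_EDGE_WEIGHT)
    elif correction == "translation":
        # |W| / area of the window shifted by the pair's displacement
        dx = np.abs(points[ii, 0] - points[jj, 0])
        dy = np.abs(points[ii, 1] - points[jj, 1])
        w = area / ((window.width - dx) * (window.height - dy))
    elif correction == "none":
        w = np.ones_like(dv)
    else:
        raise ValueError(f"correction must be one of {CORRECTIONS}, got {correction!r}")

    g = np.empty_like(r_grid)
    for k, r in enumerate(r_grid):
        t = (r - dv) / h
        kern = np.where(np.abs(t) < 1.0, 0.75 * (1.0 - t**2) / h, 0.0)
        g[k] = np.sum(w * kern) / (2.0 * np.pi * r * lambda2 * area)
    return PCFEstimate(
        r_grid=r_grid,
        g_values=g,
        n_points=n,
        window=window,
        bandwidth=h,
        correction=correction,
        n_pairs_used=int(dv.size),
        n_pairs_excluded=excluded,
    )


def pcf_estimate(
    plot: CensusedPlot,
    r_grid: np.ndarray | None = None,
    bandwidth: float | None = None,
    correction: str = "isotropic",
) -> PCFEstimate:
    """Edge-corrected kernel estimate of the pair correlation function.

    The estimate is species-blind: all individuals of the plot enter,
    matching the community-level neighbourhood-density usage. Defaults:
    Stoyan bandwidth from the plot's own intensity, and the standard r grid
    from that bandwidth up to a quarter of the short window side.
    """
    n = plot.n_individuals
    if n < 2:
        raise ValueError(f"plot {plot.plot_id!r}: pcf needs >= 2 points, has {n}")
    if bandwidth is None:
        bandwidth = stoyan_bandwidth(n / plot.window.area)
    if r_grid is None:
        r_grid = default_r_grid(plot.window, bandwidth)
    return _pcf_from_points(plot.coordinates(), plot.window, np.asarray(r_grid, float), bandwidth, correction)


@dataclass(frozen=True)
class DeltaPCFCurve:
    """Per-plot change in relative neighbourhood density, g_t2 - g_t1."""

    plot_id: str
    r_grid: np.ndarray
    delta: np.ndarray
    bandwidth: float
    n_t1: int
    n_t2: int


def delta_pcf(
    plot_t1: CensusedPlot,
    plot_t2: CensusedPlot,
    r_grid: np.ndarray | None = None,
    bandwidth: float | None = None,
    correction: str = "isotropic",
) -> DeltaPCFCurve:
    """Pointwise g_t2(r) - g_t1(r) on a shared grid and shared bandwidth.

    A single bandwidth, from the pooled intensity of both censuses, is used
    for both estimates so the difference is not confounded by a bandwidth
    change between censuses.
    """
    if plot_t1.n_individuals < 2 or plot_t2.n_individuals < 2:
        raise ValueError(
            f"plot {plot_t1.plot_id!r}: both censuses need >= 2 points "
            f"(n_t1={plot_t1.n_individuals}, n_t2={plot_t2.n_individuals})"
        )
    area = plot_t1.window.area
    if bandwidth is None:
        pooled_intensity = (plot_t1.n_individuals + plot_t2.n_individuals) / (2.0 * area)
        bandwidth = stoyan_bandwidth(pooled_intensity)
    if r_grid is None:
        r_grid = default_r_grid(plot_t1.window, bandwidth)
    r_grid = np.asarray(r_grid, dtype=float)
    g1 = _pcf_from_points(plot_t1.coordinates(), plot_t1.window, r_grid, bandwidth, correction)
    g2 = _pcf_from_points(plot_t2.coordinates(), plot_t2.window, r_grid, bandwidth, correction)
    return DeltaPCFCurve(
        plot_id=plot_t1.plot_id,
        r_grid=r_grid,
        delta=g2.g_values - g1.g_values,
        bandwidth=float(bandwidth),
        n_t1=plot_t1.n_individuals,
        n_t2=plot_t2.n_individuals,
    )


@dataclass(frozen=True)
class DeltaPCFSummary:
    """Replicate-averaged change curve with a pointwise band."""

    r_grid: np.ndarray
    mean_delta: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_replicates: int
    band_type: str


def replicate_band(curves: Sequence[DeltaPCFCurve], band_type: str = "t_ci_95") -> DeltaPCFSummary:
    """Pointwise mean and band of replicate change curves.

    band_type "t_ci_95": mean +/- t_{0.975, n-1} * SE (the 95% confidence
    interval of the replicate mean); "mean_pm_1sd": mean +/- one standard
    deviation across replicates. All curves must share the r grid.
    """
    if len(curves) < 2:
        raise ValueError("replicate band needs >= 2 curves")
    if band_type not in BAND_TYPES:
        raise ValueError(f"band_type must be one of {BAND_TYPES}, got {band_type!r}")
    r0 = curves[0].r_grid
    for c in curves[1:]:
        if c.r_grid.shape != r0.shape or not np.allclose(c.r_grid, r0):
            raise ValueError("replicate curves were computed on different r grids")
    mat = np.vstack([c.delta for c in curves])
    n = mat.shape[0]
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1)
    if band_type == "t_ci_95":
        half = scipy.stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
    else:
        half = sd
    return DeltaPCFSummary(
        r_grid=r0,
        mean_delta=mean,
        ci_low=mean - half,
        ci_high=mean + half,
        n_replicates=n,
        band_type=band_type,
    )


def classify_interactions(summary: DeltaPCFSummary) -> np.ndarray:
    """Sign rule per radius: the whole band below zero -> "negative"
    (competition), entirely above -> "positive" (facilitation), else "none".
    """
    calls = np.full(summary.r_grid.shape, "none", dtype=object)
    calls[summary.ci_high < 0] = "negative"
    calls[summary.ci_low > 0] = "positive"
    return calls


def delta_pcf_by_treatment(
    experiment: Experiment,
    r_grid: np.ndarray | None = None,
    bandwidth: float | None = None,
    correction: str = "isotropic",
    band_type: str = "t_ci_95",
) -> dict[str, DeltaPCFSummary]:
    """Replicate-band summaries per shading treatment.

    One shared bandwidth and r grid — derived from the experiment-wide mean
    pooled intensity unless given — keep treatments comparable. Plots with
    fewer than two individuals at either census are excluded with a logged
    reason.
    """
    experiment.validate()
    pairs = [(t1, t2) for t1, t2 in experiment.census_pairs()]
    usable = []
    for t1, t2 in pairs:
        if t1.n_individuals < 2 or t2.n_individuals < 2:
            logger.info(
                "delta_pcf: excluding plot %s (<2 individuals at a census)", t1.plot_id
            )
            continue
        usable.append((t1, t2))
    if not usable:
        raise ValueError("no plot has >= 2 individuals at both censuses")
    if bandwidth is None:
        area = usable[0][0].window.area
        mean_intensity = float(
            np.mean([(a.n_individuals + b.n_individuals) / (2 * area) for a, b in usable])
        )
        bandwidth = stoyan_bandwidth(mean_intensity)
    if r_grid is None:
        r_grid = default_r_grid(usable[0][0].window, bandwidth)
    out: dict[str, DeltaPCFSummary] = {}
    for treatment in experiment.treatments():
        curves = [
            delta_pcf(t1, t2, r_grid=r_grid, bandwidth=bandwidth, correction=correction)
            for t1, t2 in usable
            if t1.treatment == treatment
        ]
        if len(curves) >= 2:
            out[treatment] = replicate_band(curves, band_type=band_type)
        else:
            logger.info("delta_pcf: treatment %r has < 2 usable replicates, skipped", treatment)
    return out
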
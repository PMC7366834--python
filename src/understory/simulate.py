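"""Synthetic two-census shading experiments.

The generator emulates a blocked field design: ``n_blocks`` blocks, each
holding one plot per shading treatment, all regenerating from one shared
seed bank. The first census draws, for every plot, a Poisson number of
individuals whose species labels are i.i.d. from the seed-bank relative
abundances and whose positions follow either complete spatial randomness
(CSR) or a Thomas-style cluster process. Between censuses every individual
survives independently with probability

    p_surv = p0 * F^phi * C,        capped at 1,

where ``F = exp(-(L - mu_s)^2 / (2 sigma_s^2))`` is a Gaussian light-match
factor (L the plot treatment's illumination, mu_s / sigma_s the species'
light optimum and tolerance), ``phi >= 0`` scales the strength of light
filtering, and ``C = exp(-c * n_r)`` is a crowding factor driven by the
number of neighbours within radius ``r_c`` at the first census (c < 0 gives
facilitation). With ``phi = c = 0`` the dynamics reduce to pure binomial
thinning, which anchors the generator's statistical tests.

All randomness flows from one root seed, split deterministically per stage
(pool, initial census, dynamics), so a fixed seed reproduces the experiment
byte-for-byte through :func:`understory.data.write_census`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy.spatial import cKDTree

from .data import (
    DEFAULT_LIGHT_MAP,
    CensusedPlot,
    Experiment,
    IndividualRecord,
    RectWindow,
)

__all__ = [
    "SpeciesPool",
    "SimulationConfig",
    "build_species_pool",
    "simulate_initial_census",
    "simulate_dynamics",
    "simulate_exchangeable_censuses",
    "generate_experiment",
]


@dataclass(frozen=True)
class SpeciesPool:
    """Shared seed bank: relative abundances and light-response traits."""

    species_ids: tuple[str, ...]
    proportions: np.ndarray  # sums to 1
    light_optima: np.ndarray  # mu_s, mol m^-2 d^-1
    light_tolerances: np.ndarray  # sigma_s > 0, mol m^-2 d^-1

    def __post_init__(self) -> None:
        n = len(self.species_ids)
        for name in ("proportions", "light_optima", "light_tolerances"):
            arr = getattr(self, name)
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != {n} species")
        if abs(float(np.sum(self.proportions)) - 1.0) > 1e-12:
            raise ValueError("seed-bank proportions must sum to 1")
        if np.any(self.light_tolerances <= 0):
            raise ValueError("light tolerances must be positive")

    @property
    def n_species(self) -> int:
        return len(self.species_ids)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic experiment.

    Defaults reproduce the reference blocked design: 12 blocks x 4 shading
    treatments (48 plots of 1.1 x 0.9 m), a 39-species pool, and an initial
    density chosen so the experiment starts with ~47,322 individuals overall.
    Only the strong-shade illumination (10 mol m^-2 d^-1) is a field value;
    the lighter treatments form an assumed evenly spaced gradient. Baseline
    survival, filtering strength and crowding strength are calibrated so
    default expected overall survival is near the observed ~0.59
    (47,322 -> 28,037 individuals over one growing season).
    """

    n_blocks: int = 12
    light_map: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LIGHT_MAP))
    window: RectWindow = field(default_factory=lambda: RectWindow(1.1, 0.9))
    n_species: int = 39
    abundance_model: Literal["lognormal", "uniform"] = "lognormal"
    lognormal_sigma: float = 1.0
    #: individuals per m^2 at the first census; default gives E[plot count]
    #: = 47322/48 in a 0.99 m^2 window.
    initial_density: float = 47_322 / 48 / (1.1 * 0.9)
    spatial_model: Literal["csr", "thomas"] = "csr"
    thomas_parent_intensity: float = 50.0  # parents per m^2
    thomas_cluster_sd: float = 0.03  # metres
    filtering_strength: float = 0.4  # phi
    competition_strength: float = 0.015  # c; negative -> facilitation
    competition_radius: float = 0.05  # r_c, metres
    baseline_survival: float = 0.95  # p0
    recruitment_rate: float = 0.0  # recruits per m^2 between censuses
    tolerance_range: tuple[float, float] = (5.0, 15.0)  # sigma_s ~ U[range]
    optimum_range: tuple[float, float] | None = None  # default: light_map span
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if self.n_species < 1:
            raise ValueError("species pool must contain at least one species")
        if not self.light_map:
            raise ValueError("light_map must name at least one treatment")
        if self.initial_density <= 0:
            raise ValueError("initial_density must be positive")
        if self.competition_radius <= 0:
            raise ValueError("competition_radius must be positive")
        if not (0.0 < self.baseline_survival <= 1.0):
            raise ValueError("baseline_survival must be in (0, 1]")
        if self.filtering_strength < 0:
            raise ValueError("filtering_strength must be >= 0")
        if self.abundance_model not in ("lognormal", "uniform"):
            raise ValueError(f"unknown abundance model {self.abundance_model!r}")
        if self.spatial_model not in ("csr", "thomas"):
            raise ValueError(f"unknown spatial model {self.spatial_model!r}")
        lo, hi = self.tolerance_range
        if not (0 < lo <= hi):
            raise ValueError("tolerance_range must be positive and ordered")

    def resolved_optimum_range(self) -> tuple[float, float]:
        if self.optimum_range is not None:
            return self.optimum_range
        values = list(self.light_map.values())
        return (min(values), max(values))


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    """Deterministic per-stage RNG split from the root seed."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stage,)))


def build_species_pool(config: SimulationConfig, rng: np.random.Generator | None = None) -> SpeciesPool:
    """Draw the shared seed bank from the configured abundance model.

    Relative abundances come from a lognormal (classic rank-abundance shape)
    or uniform model and are normalised to sum to 1; light optima are uniform
    over the experiment's illumination span and tolerances uniform over
    ``tolerance_range``. Fully determined by ``config.rng_seed``.
    """
    config.validate()
    if rng is None:
        rng = _stage_rng(config.rng_seed, 0)
    s = config.n_species
    if config.abundance_model == "lognormal":
        raw = rng.lognormal(mean=0.0, sigma=config.lognormal_sigma, size=s)
    else:
        raw = rng.uniform(0.5, 1.5, size=s)
    props = raw / raw.sum()
    lo, hi = config.resolved_optimum_range()
    optima = rng.uniform(lo, hi, size=s)
    t_lo, t_hi = config.tolerance_range
    tolerances = rng.uniform(t_lo, t_hi, size=s)
    width = len(str(s))
    ids = tuple(f"sp{i + 1:0{width}d}" for i in range(s))
    return SpeciesPool(ids, props, optima, tolerances)


def _csr_positions(n: int, window: RectWindow, rng: np.random.Generator) -> np.ndarray:
    return np.column_stack(
        [rng.uniform(0.0, window.width, size=n), rng.uniform(0.0, window.height, size=n)]
    )


def _thomas_positions(n: int, config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Clustered positions: each point joins a random Gaussian cluster.

    Cluster centres are a Poisson sample of intensity ``thomas_parent_intensity``
    inside the window; each of the n points picks a centre uniformly and adds
    an isotropic Gaussian offset of sd ``thomas_cluster_sd``, resampling until
    it lands inside the window. Conditioning on n keeps the shared-seed-bank
    count model (Poisson plot totals) intact.
    """
    window = config.window
    n_parents = max(1, int(rng.poisson(config.thomas_parent_intensity * window.area)))
    parents = _csr_positions(n_parents, window, rng)
    out = np.empty((n, 2), dtype=float)
    filled = 0
    while filled < n:
        need = n - filled
        idx = rng.integers(0, n_parents, size=need)
        pts = parents[idx] + rng.normal(0.0, config.thomas_cluster_sd, size=(need, 2))
        ok = (
            (pts[:, 0] >= 0)
            & (pts[:, 0] <= window.width)
            & (pts[:, 1] >= 0)
            & (pts[:, 1] <= window.height)
        )
        kept = pts[ok]
        out[filled : filled + len(kept)] = kept
        filled += len(kept)
    return out


def _draw_plot(
    plot_id: str,
    block_id: str,
    treatment: str,
    census: str,
    pool: SpeciesPool,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> CensusedPlot:
    n = int(rng.poisson(config.initial_density * config.window.area))
    species_idx = rng.choice(pool.n_species, size=n, p=pool.proportions)
    if config.spatial_model == "csr":
        pos = _csr_positions(n, config.window, rng)
    else:
        pos = _thomas_positions(n, config, rng)
    individuals = [
        IndividualRecord(pool.species_ids[k], float(x), float(y))
        for k, (x, y) in zip(species_idx, pos)
    ]
    return CensusedPlot(plot_id, block_id, treatment, census, config.window, individuals)


def _layout(config: SimulationConfig) -> list[tuple[str, str, str]]:
    """(plot_id, block_id, treatment) for the blocked design."""
    out = []
    for b in range(1, config.n_blocks + 1):
        block_id = f"b{b:02d}"
        for treatment in config.light_map:
            out.append((f"{block_id}-{treatment}", block_id, treatment))
    return out


def simulate_initial_census(
    pool: SpeciesPool, config: SimulationConfig, rng: np.random.Generator | None = None
) -> Experiment:
    """Germination census (t1): every plot draws from the shared seed bank."""
    config.validate()
    if rng is None:
        rng = _stage_rng(config.rng_seed, 1)
    plots = [
        _draw_plot(pid, bid, trt, "t1", pool, config, rng) for pid, bid, trt in _layout(config)
    ]
    return Experiment(plots=plots, light_map=dict(config.light_map))


def _survival_probability(
    plot: CensusedPlot, pool: SpeciesPool, config: SimulationConfig
) -> np.ndarray:
    """Per-individual survival probability p0 * F^phi * C, capped at 1."""
    n = plot.n_individuals
    if n == 0:
        return np.empty(0, dtype=float)
    light = config.light_map[plot.treatment]
    idx = {sid: k for k, sid in enumerate(pool.species_ids)}
    k = np.array([idx[ind.species_id] for ind in plot.individuals])
    mu = pool.light_optima[k]
    sigma = pool.light_tolerances[k]
    match = np.exp(-((light - mu) ** 2) / (2.0 * sigma**2))
    p = config.baseline_survival * match**config.filtering_strength
    if config.competition_strength != 0.0:
        pos = plot.coordinates()
        tree = cKDTree(pos)
        # neighbour counts at t1, before any deaths (self excluded)
        n_r = tree.query_ball_point(pos, r=config.competition_radius, return_length=True) - 1
        p = p * np.exp(-config.competition_strength * n_r)
    return np.minimum(p, 1.0)


def simulate_dynamics(
    experiment_t1: Experiment, pool: SpeciesPool, config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> Experiment:
    """Apply light- and crowding-dependent mortality; return both censuses.

    Each individual survives independently given the t1 configuration;
    survivors keep their coordinates. Optional recruitment re-draws new
    individuals from the seed bank at ``recruitment_rate`` per m^2 (off by
    default). A plot emptied entirely is retained, with a warning.
    """
    config.validate()
    if rng is None:
        rng = _stage_rng(config.rng_seed, 2)
    plots: list[CensusedPlot] = []
    for t1 in sorted(
        (p for p in experiment_t1.plots if p.census == "t1"), key=lambda p: p.plot_id
    ):
        p_surv = _survival_probability(t1, pool, config)
        alive = rng.random(t1.n_individuals) < p_surv
        survivors = [ind for ind, keep in zip(t1.individuals, alive) if keep]
        if config.recruitment_rate > 0:
            n_new = int(rng.poisson(config.recruitment_rate * config.window.area))
            sp = rng.choice(pool.n_species, size=n_new, p=pool.proportions)
            pos = _csr_positions(n_new, config.window, rng)
            survivors.extend(
                IndividualRecord(pool.species_ids[k], float(x), float(y))
                for k, (x, y) in zip(sp, pos)
            )
        if t1.n_individuals > 0 and not survivors:
            import logging

            logging.getLogger(__name__).warning(
                "plot %s lost all individuals between censuses", t1.plot_id
            )
        plots.append(
            CensusedPlot(t1.plot_id, t1.block_id, t1.treatment, "t2", t1.window, survivors)
        )
    out = Experiment(
        plots=[p for p in experiment_t1.plots if p.census == "t1"] + plots,
        light_map=dict(config.light_map),
    )
    return out


def simulate_exchangeable_censuses(
    pool: SpeciesPool, config: SimulationConfig, rng: np.random.Generator | None = None
) -> Experiment:
    """Calibration null: t1 and t2 are independent equal-intensity draws.

    Under the generator's mortality null (phi = c = 0, p0 < 1) the second
    census is a smaller sample than the first, which alone raises expected
    Bray–Curtis dissimilarity; the change statistic then has positive mean
    without any ecology. This helper instead makes the two censuses
    exchangeable — independent draws from the same seed bank at the same
    intensity — so the change statistic has exactly zero mean and the
    one-sample t test's size can be checked at its nominal level.
    """
    config.validate()
    if rng is None:
        rng = _stage_rng(config.rng_seed, 3)
    plots = []
    for pid, bid, trt in _layout(config):
        for census in ("t1", "t2"):
            plots.append(_draw_plot(pid, bid, trt, census, pool, config, rng))
    return Experiment(plots=plots, light_map=dict(config.light_map))


def generate_experiment(config: SimulationConfig | None = None) -> Experiment:
    """One-call default emulation: pool -> germination -> mortality."""
    if config is None:
        config = SimulationConfig()
    config.validate()
    pool = build_species_pool(config)
    t1 = simulate_initial_census(pool, config)
    return simulate_dynamics(t1, pool, config)
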
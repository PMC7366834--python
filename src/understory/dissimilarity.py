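"""Compositional-dissimilarity dynamics and their inference.

The central statistic is the change in Bray–Curtis dissimilarity between a
pair of communities across two censuses,

    delta_B(j, k) = B_t2(j, k) - B_t1(j, k),

positive when communities j and k became more dissimilar. Pairs are grouped
by whether the two plots share a shading treatment (light filtering predicts
divergence between treatments, i.e. delta_B > 0 for different-treatment
pairs) and the group means are tested against zero with Student's t tests;
between-treatment divergence is regressed on the pairwise illumination
difference.

Pairwise delta_B values are not independent — every plot enters many pairs.
The plain t tests reproduce the field's standard procedure; a block-level
permutation test (treatment labels reshuffled within blocks) is available
as a robustness check and is reported separately.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from scipy.spatial.distance import braycurtis as _braycurtis

from .data import (
    DEFAULT_SUBPLOT_GRID,
    CensusedPlot,
    DegenerateSampleError,
    Experiment,
    abundance_vector,
    split_into_subplots,
)

logger = logging.getLogger(__name__)

GROUP_SAME = "same_treatment"
GROUP_DIFFERENT = "different_treatment"
GROUP_SUBPLOT = "within_plot_subplots"

RECORD_COLUMNS = ["unit_a", "unit_b", "group", "B_t1", "B_t2", "delta_B", "light_diff"]


def bray_curtis(x: Mapping[str, float], y: Mapping[str, float]) -> float:
    """Bray–Curtis dissimilarity sum|x_i - y_i| / sum(x_i + y_i).

    Taken over the union of species; 0 for identical abundance vectors,
    1 for disjoint species sets. Undefined (raises) if either community
    is empty.
    """
    tx = sum(x.values())
    ty = sum(y.values())
    if tx <= 0 or ty <= 0:
        raise ValueError("Bray–Curtis is undefined for an empty community")
    species = sorted(set(x) | set(y))
    u = np.array([x.get(s, 0.0) for s in species], dtype=float)
    v = np.array([y.get(s, 0.0) for s in species], dtype=float)
    return float(_braycurtis(u, v))


def delta_dissimilarity(
    experiment: Experiment,
    level: str = "plots",
    grid: tuple[int, int] = DEFAULT_SUBPLOT_GRID,
) -> pd.DataFrame:
    """Pairwise dissimilarity-change records.

    level="plots": one record per unordered plot pair, grouped as
    same-treatment vs different-treatment, with the absolute illumination
    difference from the experiment's light map.

    level="subplots": plots are split on ``grid`` (default 3 x 2 = 6
    subplots) and records cover only subplot pairs *within* a plot
    (group ``within_plot_subplots``, light_diff 0).

    Pairs in which any of the four communities (either unit at either
    census) is empty are dropped; the count is logged and stored in
    ``df.attrs["n_dropped_pairs"]``.
    """
    experiment.validate()
    units: list[tuple[str, str, float, Counter, Counter]] = []
    pair_iter: list[tuple[int, int]] = []
    if level == "plots":
        for t1, t2 in experiment.census_pairs():
            units.append(
                (t1.plot_id, t1.treatment, experiment.light_map[t1.treatment],
                 abundance_vector(t1), abundance_vector(t2))
            )
        pair_iter = list(itertools.combinations(range(len(units)), 2))
    elif level == "subplots":
        for t1, t2 in experiment.census_pairs():
            start = len(units)
            subs_t1 = split_into_subplots(t1, *grid)
            subs_t2 = split_into_subplots(t2, *grid)
            for s1, s2 in zip(subs_t1, subs_t2):
                units.append(
                    (s1.plot_id, s1.treatment, experiment.light_map[s1.treatment],
                     abundance_vector(s1), abundance_vector(s2))
                )
            pair_iter.extend(itertools.combinations(range(start, len(units)), 2))
    else:
        raise ValueError(f"level must be 'plots' or 'subplots', got {level!r}")

    rows = []
    dropped = 0
    for i, j in pair_iter:
        id_a, trt_a, light_a, a1, a2 = units[i]
        id_b, trt_b, light_b, b1, b2 = units[j]
        if min(sum(a1.values()), sum(a2.values()), sum(b1.values()), sum(b2.values())) == 0:
            dropped += 1
            continue
        b_t1 = bray_curtis(a1, b1)
        b_t2 = bray_curtis(a2, b2)
        if level == "subplots":
            group = GROUP_SUBPLOT
        else:
            group = GROUP_SAME if trt_a == trt_b else GROUP_DIFFERENT
        rows.append(
            (id_a, id_b, group, b_t1, b_t2, b_t2 - b_t1, abs(light_a - light_b))
        )
    if dropped:
        logger.info("delta_dissimilarity: dropped %d pair(s) with an empty community", dropped)
    df = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    df.attrs["n_dropped_pairs"] = dropped
    return df


# ---------------------------------------------------------------------------
# Inference


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    degrees_of_freedom: float
    p_value: float
    group_means: tuple[float, ...]
    standard_error: float
    n: tuple[int, ...]


def one_sample_ttest(deltas: Sequence[float]) -> TTestResult:
    """Classical one-sample Student's t test of mean(delta_B) against zero."""
    x = np.asarray(deltas, dtype=float)
    if x.size < 2:
        raise ValueError(f"one-sample t test needs n >= 2, got n = {x.size}")
    if np.all(x == x[0]):
        raise DegenerateSampleError("sample variance is zero")
    res = scipy.stats.ttest_1samp(x, popmean=0.0)
    se = float(np.std(x, ddof=1) / np.sqrt(x.size))
    return TTestResult(
        statistic=float(res.statistic),
        degrees_of_freedom=float(x.size - 1),
        p_value=float(res.pvalue),
        group_means=(float(x.mean()),),
        standard_error=se,
        n=(int(x.size),),
    )


def two_sample_ttest(
    deltas_a: Sequence[float], deltas_b: Sequence[float], equal_var: bool = True
) -> TTestResult:
    """Two-sample t test of group means (pooled variance by default).

    ``equal_var=False`` switches to Welch's unequal-variance form.
    """
    a = np.asarray(deltas_a, dtype=float)
    b = np.asarray(deltas_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if np.all(a == a[0]) and np.all(b == b[0]):
        raise DegenerateSampleError("both sample variances are zero")
    res = scipy.stats.ttest_ind(a, b, equal_var=equal_var)
    if equal_var:
        sp2 = ((a.size - 1) * np.var(a, ddof=1) + (b.size - 1) * np.var(b, ddof=1)) / (
            a.size + b.size - 2
        )
        se = float(np.sqrt(sp2 * (1.0 / a.size + 1.0 / b.size)))
    else:
        se = float(np.sqrt(np.var(a, ddof=1) / a.size + np.var(b, ddof=1) / b.size))
    return TTestResult(
        statistic=float(res.statistic),
        degrees_of_freedom=float(res.df),
        p_value=float(res.pvalue),
        group_means=(float(a.mean()), float(b.mean())),
        standard_error=se,
        n=(int(a.size), int(b.size)),
    )


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of delta_B on illumination difference."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float  # two-sided, slope
    n: int
    conf_band: pd.DataFrame  # columns light_diff, fit, ci_low, ci_high (95% pointwise)


def regress_delta_on_light(
    records: pd.DataFrame, aggregate: str | None = None
) -> RegressionResult:
    """OLS of delta_B on light_diff over different-treatment pairs.

    ``aggregate="treatment_pairs"`` first averages delta_B within each
    unordered treatment pair (one point per distinct illumination contrast);
    the default uses every plot pair. Returns slope, intercept, R^2, the
    slope's two-sided p value and the 95% pointwise confidence band of the
    fitted mean.
    """
    df = records
    if "group" in df.columns:
        df = df[df["group"] == GROUP_DIFFERENT]
    if aggregate == "treatment_pairs":
        df = df.groupby("light_diff", as_index=False)["delta_B"].mean()
    elif aggregate is not None:
        raise ValueError(f"unknown aggregation {aggregate!r}")
    x = df["light_diff"].to_numpy(dtype=float)
    y = df["delta_B"].to_numpy(dtype=float)
    if x.size < 3:
        raise ValueError(f"regression needs >= 3 records, got {x.size}")
    if np.unique(x).size < 2:
        raise ValueError("all illumination differences are equal: design is rank-deficient")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    grid = np.linspace(x.min(), x.max(), 50)
    pred = model.get_prediction(sm.add_constant(grid))
    ci = pred.conf_int(alpha=0.05)
    band = pd.DataFrame(
        {"light_diff": grid, "fit": pred.predicted_mean, "ci_low": ci[:, 0], "ci_high": ci[:, 1]}
    )
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        p_value=float(model.pvalues[1]),
        n=int(x.size),
        conf_band=band,
    )


@dataclass(frozen=True)
class PermutationResult:
    statistic: float
    p_value: float
    n_permutations: int


def block_permutation_test(
    experiment: Experiment,
    records: pd.DataFrame | None = None,
    n_permutations: int = 999,
    seed: int = 0,
) -> PermutationResult:
    """Blocked permutation check of the different-vs-same-treatment contrast.

    Pairwise delta_B values share plots and are therefore non-independent;
    the plain two-sample t test ignores this. Here treatment labels are
    reshuffled independently within every block (respecting the randomized
    block design), the same/different grouping is recomputed, and the
    two-sample t statistic is re-evaluated; the p value is the fraction of
    permutations (plus the observed labelling) with |t| at least as large
    as observed.
    """
    if records is None:
        records = delta_dissimilarity(experiment, level="plots")
    meta = {}
    for t1, _ in experiment.census_pairs():
        meta[t1.plot_id] = (t1.block_id, t1.treatment)
    pair_ids = records[["unit_a", "unit_b"]].to_numpy()
    deltas = records["delta_B"].to_numpy(dtype=float)

    def t_stat(labels: dict[str, str]) -> float:
        same = np.array([labels[a] == labels[b] for a, b in pair_ids])
        da, db = deltas[~same], deltas[same]
        if da.size < 2 or db.size < 2:
            return np.nan
        return two_sample_ttest(da, db).statistic

    observed = t_stat({pid: trt for pid, (_, trt) in meta.items()})
    rng = np.random.default_rng(seed)
    blocks: dict[str, list[str]] = {}
    for pid, (bid, _) in meta.items():
        blocks.setdefault(bid, []).append(pid)
    hits = 0
    for _ in range(n_permutations):
        labels = {}
        for bid, pids in blocks.items():
            trts = [meta[p][1] for p in pids]
            perm = rng.permutation(len(trts))
            for p, k in zip(pids, perm):
                labels[p] = trts[k]
        t = t_stat(labels)
        if not np.isnan(t) and abs(t) >= abs(observed):
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return PermutationResult(statistic=float(observed), p_value=float(p), n_permutations=n_permutations)
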
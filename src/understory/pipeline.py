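"""End-to-end orchestration: acquire data, analyse, report.

One :class:`AnalysisConfig` drives the whole re-enactment: read a census
file (or simulate one), compute plot- and subplot-level dissimilarity
dynamics with their t tests and the illumination regression, per-treatment
change-in-neighbourhood-density bands with interaction calls, and
per-treatment diversity-change summaries. Outputs are plain CSV tables plus
one JSON manifest that records the resolved configuration, the seed and
exclusion counts, so any run can be reproduced bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data import (
    DEFAULT_SUBPLOT_GRID,
    Experiment,
    abundance_vector,
    diversity_indices,
    read_census,
    write_census,
)
from .dissimilarity import (
    GROUP_DIFFERENT,
    GROUP_SAME,
    GROUP_SUBPLOT,
    block_permutation_test,
    delta_dissimilarity,
    one_sample_ttest,
    regress_delta_on_light,
    two_sample_ttest,
)
from .pointpattern import classify_interactions, delta_pcf_by_treatment
from .simulate import SimulationConfig, generate_experiment

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """What to analyse and how; exactly one data source must be set."""

    census_path: str | Path | None = None
    simulation: SimulationConfig | None = None
    subplot_grid: tuple[int, int] = DEFAULT_SUBPLOT_GRID
    r_grid: np.ndarray | None = None
    bandwidth: float | None = None
    band_type: str = "t_ci_95"
    welch: bool = False
    permutation: bool = False
    n_permutations: int = 999
    aggregate_regression: str | None = None
    outdir: str | Path | None = None
    seed: int = 0

    def validate(self) -> None:
        if (self.census_path is None) == (self.simulation is None):
            raise ValueError("exactly one of census_path / simulation must be set")


@dataclass
class ReportBundle:
    """All result tables of one run, plus the reproducibility manifest."""

    pair_records: pd.DataFrame
    subplot_records: pd.DataFrame
    tests: pd.DataFrame
    regression: pd.DataFrame
    regression_band: pd.DataFrame
    delta_pcf: pd.DataFrame
    interaction_calls: pd.DataFrame
    diversity_plots: pd.DataFrame
    diversity_treatments: pd.DataFrame
    manifest: dict


def diversity_change_summary(experiment: Experiment) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-plot diversity indices at both censuses and their changes,
    plus per-treatment means and standard errors of the changes.

    Plots empty at a census get NaN index values for that census (flagged
    via the NaNs themselves); they still appear in the per-plot table.
    """
    rows = []
    for t1, t2 in experiment.census_pairs():
        rec: dict = {"plot_id": t1.plot_id, "block_id": t1.block_id, "treatment": t1.treatment}
        for census, plot in (("t1", t1), ("t2", t2)):
            counts = abundance_vector(plot)
            if sum(counts.values()) == 0:
                vals = dict(richness=np.nan, shannon=np.nan, simpson=np.nan, pielou=np.nan)
            else:
                summ = diversity_indices(counts)
                vals = dict(
                    richness=summ.richness, shannon=summ.shannon,
                    simpson=summ.simpson, pielou=summ.pielou,
                )
            for k, v in vals.items():
                rec[f"{k}_{census}"] = v
        for k in ("richness", "shannon", "simpson", "pielou"):
            rec[f"delta_{k}"] = rec[f"{k}_t2"] - rec[f"{k}_t1"]
        rows.append(rec)
    per_plot = pd.DataFrame(rows).sort_values("plot_id").reset_index(drop=True)
    deltas = [f"delta_{k}" for k in ("richness", "shannon", "simpson", "pielou")]
    per_treatment = (
        per_plot.groupby("treatment")[deltas]
        .agg(["mean", "sem"])
        .pipe(lambda df: df.set_axis(["_".join(c) for c in df.columns], axis=1))
        .reset_index()
    )
    return per_plot, per_treatment


def _tests_table(pair_records: pd.DataFrame, subplot_records: pd.DataFrame, welch: bool) -> pd.DataFrame:
    rows = []
    by_group = {
        GROUP_SAME: pair_records.loc[pair_records["group"] == GROUP_SAME, "delta_B"],
        GROUP_DIFFERENT: pair_records.loc[pair_records["group"] == GROUP_DIFFERENT, "delta_B"],
        GROUP_SUBPLOT: subplot_records["delta_B"] if len(subplot_records) else pd.Series(dtype=float),
    }
    for group, deltas in by_group.items():
        if len(deltas) >= 2 and deltas.var(ddof=1) > 0:
            res = one_sample_ttest(deltas)
            rows.append(
                dict(test="one_sample", group=group, n=len(deltas), mean_delta_B=res.group_means[0],
                     t=res.statistic, df=res.degrees_of_freedom, p=res.p_value)
            )
        else:
            rows.append(
                dict(test="one_sample", group=group, n=len(deltas),
                     mean_delta_B=float(deltas.mean()) if len(deltas) else np.nan,
                     t=np.nan, df=np.nan, p=np.nan)
            )
    da = by_group[GROUP_DIFFERENT]
    db = by_group[GROUP_SAME]
    if len(da) >= 2 and len(db) >= 2:
        res = two_sample_ttest(da, db, equal_var=not welch)
        rows.append(
            dict(test="two_sample_different_vs_same", group="different_vs_same",
                 n=len(da) + len(db), mean_delta_B=res.group_means[0] - res.group_means[1],
                 t=res.statistic, df=res.degrees_of_freedom, p=res.p_value)
        )
    return pd.DataFrame(rows)


def run(config: AnalysisConfig) -> ReportBundle:
    """Execute the full analysis; write tables + manifest if outdir is set."""
    config.validate()
    stage = "acquire"
    try:
        if config.simulation is not None:
            sim = dataclasses.replace(config.simulation)
            experiment = generate_experiment(sim)
            source = {"simulation": _jsonable(sim)}
        else:
            experiment = read_census(config.census_path)
            source = {"census_path": str(config.census_path)}
        experiment.validate()

        stage = "dissimilarity"
        pair_records = delta_dissimilarity(experiment, level="plots")
        subplot_records = delta_dissimilarity(experiment, level="subplots", grid=config.subplot_grid)
        tests = _tests_table(pair_records, subplot_records, config.welch)
        if config.permutation:
            perm = block_permutation_test(
                experiment, pair_records, n_permutations=config.n_permutations, seed=config.seed
            )
            tests = pd.concat(
                [tests, pd.DataFrame([dict(
                    test="block_permutation", group="different_vs_same",
                    n=len(pair_records), mean_delta_B=np.nan,
                    t=perm.statistic, df=np.nan, p=perm.p_value,
                )])],
                ignore_index=True,
            )

        stage = "regression"
        n_diff = int((pair_records["group"] == GROUP_DIFFERENT).sum()) if len(pair_records) else 0
        distinct = pair_records.loc[pair_records["group"] == GROUP_DIFFERENT, "light_diff"].nunique()
        if n_diff >= 3 and distinct >= 2:
            reg = regress_delta_on_light(pair_records, aggregate=config.aggregate_regression)
            regression = pd.DataFrame([dict(
                slope=reg.slope, intercept=reg.intercept, r_squared=reg.r_squared,
                p=reg.p_value, n=reg.n,
            )])
            regression_band = reg.conf_band
        else:
            logger.info("regression skipped: %d between-treatment pair(s)", n_diff)
            regression = pd.DataFrame([dict(
                slope=np.nan, intercept=np.nan, r_squared=np.nan, p=np.nan, n=n_diff,
            )])
            regression_band = pd.DataFrame(columns=["light_diff", "fit", "ci_low", "ci_high"])

        stage = "point_pattern"
        summaries = delta_pcf_by_treatment(
            experiment, r_grid=config.r_grid, bandwidth=config.bandwidth,
            band_type=config.band_type,
        )
        pcf_rows, call_rows = [], []
        for treatment in sorted(summaries):
            s = summaries[treatment]
            calls = classify_interactions(s)
            for k, r in enumerate(s.r_grid):
                pcf_rows.append(dict(
                    treatment=treatment, r=r, mean_delta=s.mean_delta[k],
                    ci_low=s.ci_low[k], ci_high=s.ci_high[k],
                    n_replicates=s.n_replicates, band_type=s.band_type,
                ))
                call_rows.append(dict(treatment=treatment, r=r, classification=calls[k]))
        delta_pcf_df = pd.DataFrame(pcf_rows)
        calls_df = pd.DataFrame(call_rows)

        stage = "diversity"
        div_plots, div_treatments = diversity_change_summary(experiment)

        stage = "report"
        manifest = {
            "package": "understory",
            "version": __version__,
            "seed": config.seed,
            "source": source,
            # outdir does not affect results; keeping it out makes manifests
            # of identical runs byte-identical regardless of where they land
            "config": {k: v for k, v in _jsonable(config).items() if k != "outdir"},
            "counts": {
                "n_plots": len(experiment.plot_ids()),
                "n_blocks": len(experiment.blocks()),
                "n_treatments": len(experiment.treatments()),
                "n_individuals_t1": int(sum(
                    p.n_individuals for p in experiment.plots if p.census == "t1")),
                "n_individuals_t2": int(sum(
                    p.n_individuals for p in experiment.plots if p.census == "t2")),
                "dropped_pairs_plots": int(pair_records.attrs.get("n_dropped_pairs", 0)),
                "dropped_pairs_subplots": int(subplot_records.attrs.get("n_dropped_pairs", 0)),
            },
        }
        bundle = ReportBundle(
            pair_records=pair_records, subplot_records=subplot_records, tests=tests,
            regression=regression, regression_band=regression_band,
            delta_pcf=delta_pcf_df, interaction_calls=calls_df,
            diversity_plots=div_plots, diversity_treatments=div_treatments,
            manifest=manifest,
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    if config.outdir is not None:
        _write_bundle(bundle, Path(config.outdir), experiment)
    return bundle


def _write_bundle(bundle: ReportBundle, outdir: Path, experiment: Experiment) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    tables = {
        "pair_dissimilarity.csv": bundle.pair_records,
        "subplot_dissimilarity.csv": bundle.subplot_records,
        "dissimilarity_tests.csv": bundle.tests,
        "light_regression.csv": bundle.regression,
        "light_regression_band.csv": bundle.regression_band,
        "delta_pcf.csv": bundle.delta_pcf,
        "interaction_calls.csv": bundle.interaction_calls,
        "diversity_plots.csv": bundle.diversity_plots,
        "diversity_treatments.csv": bundle.diversity_treatments,
    }
    for name, df in tables.items():
        df.to_csv(outdir / name, index=False)
    write_census(experiment, outdir / "census.csv")
    (outdir / "manifest.json").write_text(
        json.dumps(bundle.manifest, indent=2, sort_keys=True, default=_json_default) + "\n"
    )
    logger.info("wrote %d tables to %s", len(tables) + 2, outdir)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _jsonable(obj) -> dict:
    if dataclasses.is_dataclass(obj):
        out = {}
        for f in dataclasses.fields(obj):
            v = getattr(obj, f.name)
            if dataclasses.is_dataclass(v):
                v = _jsonable(v)
            elif isinstance(v, np.ndarray):
                v = v.tolist()
            elif isinstance(v, Path):
                v = str(v)
            elif isinstance(v, tuple):
                v = list(v)
            out[f.name] = v
        return out
    return obj
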
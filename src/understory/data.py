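"""Data model and I/O for mapped two-census plot experiments.

A shading experiment is a collection of rectangular plots, each censused
twice (labels ``t1`` and ``t2``). Every individual carries a species label
and (x, y) coordinates in metres, with the origin at the plot's lower-left
corner. Plots belong to blocks and shading treatments, and the experiment
carries a map from treatment name to daily illumination
(mol photons m^-2 d^-1) whose pairwise differences drive the
dissimilarity-vs-light regression downstream.

Census files are plain CSV with columns
``plot_id,block_id,treatment,census,species_id,x,y``; window dimensions and
the illumination map travel in a JSON sidecar (``<stem>.meta.json``) so a
written experiment round-trips without extra arguments.
"""

from __future__ import annotations

import json
import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CENSUS_COLUMNS = ["plot_id", "block_id", "treatment", "census", "species_id", "x", "y"]
CENSUS_LABELS = ("t1", "t2")

#: Default treatment -> illumination map (mol m^-2 d^-1). Only the strong-shade
#: value is a measured quantity for subtropical-forest understory; the other
#: three form an assumed evenly spaced gradient and are fully configurable.
DEFAULT_LIGHT_MAP = {"no": 40.0, "low": 30.0, "moderate": 20.0, "strong": 10.0}

#: Default subplot grid (columns, rows): six subplots per plot.
DEFAULT_SUBPLOT_GRID = (3, 2)


class CensusFormatError(ValueError):
    """Malformed census file (missing column, bad census label, ...)."""


class CensusValidationError(ValueError):
    """Structurally valid file whose content violates an invariant."""


class PairingError(CensusValidationError):
    """A plot is present at only one of the two censuses."""


class DegenerateSampleError(ValueError):
    """A statistic was requested on a sample with no variance."""


@dataclass(frozen=True)
class RectWindow:
    """Axis-aligned rectangular observation window, metres."""

    width: float
    height: float

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise ValueError(f"window dimensions must be positive, got {self.width} x {self.height}")

    @property
    def area(self) -> float:
        return self.width * self.height

    def contains(self, x: float, y: float) -> bool:
        return 0.0 <= x <= self.width and 0.0 <= y <= self.height


@dataclass(frozen=True)
class IndividualRecord:
    """One mapped individual: species label plus coordinates in metres."""

    species_id: str
    x: float
    y: float

    def __post_init__(self) -> None:
        if not self.species_id:
            raise ValueError("species_id must be non-empty")


@dataclass
class CensusedPlot:
    """One plot at one census: mapped individuals inside a window."""

    plot_id: str
    block_id: str
    treatment: str
    census: str
    window: RectWindow
    individuals: list[IndividualRecord] = field(default_factory=list)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def coordinates(self) -> np.ndarray:
        """(n, 2) coordinate array (empty (0, 2) array for an empty plot)."""
        if not self.individuals:
            return np.empty((0, 2), dtype=float)
        return np.array([[ind.x, ind.y] for ind in self.individuals], dtype=float)

    def species(self) -> list[str]:
        return [ind.species_id for ind in self.individuals]

    def validate(self) -> None:
        if self.census not in CENSUS_LABELS:
            raise CensusValidationError(
                f"plot {self.plot_id!r}: census label {self.census!r} not in {CENSUS_LABELS}"
            )
        for i, ind in enumerate(self.individuals):
            if not self.window.contains(ind.x, ind.y):
                raise CensusValidationError(
                    f"plot {self.plot_id!r}, individual {i} ({ind.species_id!r}): "
                    f"({ind.x}, {ind.y}) outside {self.window.width} x {self.window.height} window"
                )


@dataclass
class Experiment:
    """All plots at both censuses plus the treatment -> illumination map."""

    plots: list[CensusedPlot]
    light_map: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LIGHT_MAP))

    def validate(self) -> None:
        seen: set[tuple[str, str]] = set()
        meta: dict[str, tuple[str, str]] = {}
        by_census: dict[str, set[str]] = {c: set() for c in CENSUS_LABELS}
        for plot in self.plots:
            plot.validate()
            key = (plot.plot_id, plot.census)
            if key in seen:
                raise CensusValidationError(f"duplicate plot/census pair {key}")
            seen.add(key)
            by_census[plot.census].add(plot.plot_id)
            if plot.plot_id in meta and meta[plot.plot_id] != (plot.block_id, plot.treatment):
                raise CensusValidationError(
                    f"plot {plot.plot_id!r}: block/treatment differ between censuses"
                )
            meta[plot.plot_id] = (plot.block_id, plot.treatment)
            if plot.treatment not in self.light_map:
                raise CensusValidationError(
                    f"plot {plot.plot_id!r}: treatment {plot.treatment!r} missing from light_map"
                )
        only_t1 = by_census["t1"] - by_census["t2"]
        only_t2 = by_census["t2"] - by_census["t1"]
        if only_t1 or only_t2:
            raise PairingError(
                f"plots present at a single census: t1-only {sorted(only_t1)}, t2-only {sorted(only_t2)}"
            )

    # -- lookups -----------------------------------------------------------

    def plot_ids(self) -> list[str]:
        return sorted({p.plot_id for p in self.plots})

    def treatments(self) -> list[str]:
        return sorted({p.treatment for p in self.plots})

    def blocks(self) -> list[str]:
        return sorted({p.block_id for p in self.plots})

    def get(self, plot_id: str, census: str) -> CensusedPlot:
        for p in self.plots:
            if p.plot_id == plot_id and p.census == census:
                return p
        raise KeyError(f"no plot {plot_id!r} at census {census!r}")

    def census_pairs(self) -> Iterator[tuple[CensusedPlot, CensusedPlot]]:
        """Yield (t1 plot, t2 plot) for every plot id, sorted by id."""
        for pid in self.plot_ids():
            yield self.get(pid, "t1"), self.get(pid, "t2")

    def to_frame(self) -> pd.DataFrame:
        """Canonical long-format table, deterministically sorted.

        Empty plots are kept as a single sentinel row with empty species_id
        and missing coordinates so they survive a round trip.
        """
        rows: list[tuple] = []
        for p in self.plots:
            if not p.individuals:
                rows.append((p.plot_id, p.block_id, p.treatment, p.census, "", np.nan, np.nan))
            for ind in p.individuals:
                rows.append(
                    (p.plot_id, p.block_id, p.treatment, p.census, ind.species_id, ind.x, ind.y)
                )
        df = pd.DataFrame(rows, columns=CENSUS_COLUMNS)
        return df.sort_values(
            ["plot_id", "census", "species_id", "x", "y"], kind="mergesort"
        ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# I/O


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.stem + ".meta.json")


def write_census(experiment: Experiment, path: str | Path) -> Path:
    """Write an experiment to CSV (+ JSON metadata sidecar).

    Rows are sorted by (plot_id, census, species_id, x, y) and floats use
    shortest round-trip representation, so writing is deterministic and
    write -> read -> write is byte-identical.
    """
    path = Path(path)
    experiment.validate()
    df = experiment.to_frame()
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    window = experiment.plots[0].window if experiment.plots else RectWindow(1.1, 0.9)
    meta = {
        "format": "understory-census-v1",
        "window": {"width": window.width, "height": window.height},
        "light_map": {k: float(v) for k, v in sorted(experiment.light_map.items())},
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return path


def read_census(
    path: str | Path,
    *,
    window: RectWindow | None = None,
    light_map: Mapping[str, float] | None = None,
) -> Experiment:
    """Read and validate a census CSV into an :class:`Experiment`.

    Window dimensions and the illumination map come from keyword arguments,
    else from the ``<stem>.meta.json`` sidecar, else (light map only) from
    :data:`DEFAULT_LIGHT_MAP` when every treatment in the file is a default
    treatment name. Row order in the file never affects downstream results:
    plots are rebuilt in canonical sorted order.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if (window is None or light_map is None) and sidecar.exists():
        meta = json.loads(sidecar.read_text())
        if window is None and "window" in meta:
            window = RectWindow(meta["window"]["width"], meta["window"]["height"])
        if light_map is None and "light_map" in meta:
            light_map = {str(k): float(v) for k, v in meta["light_map"].items()}

    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CENSUS_COLUMNS if c not in df.columns]
    if missing:
        raise CensusFormatError(f"census file {path} is missing column(s) {missing}")

    if window is None:
        raise CensusFormatError(
            f"no window dimensions: pass window= or provide sidecar {sidecar.name}"
        )
    if light_map is None:
        used = set(df["treatment"])
        if used <= set(DEFAULT_LIGHT_MAP):
            light_map = dict(DEFAULT_LIGHT_MAP)
        else:
            raise CensusFormatError(
                f"no light map for treatments {sorted(used - set(DEFAULT_LIGHT_MAP))}: "
                f"pass light_map= or provide sidecar {sidecar.name}"
            )

    bad = set(df["census"]) - set(CENSUS_LABELS)
    if bad:
        raise CensusFormatError(f"unknown census label(s) {sorted(bad)}; expected {CENSUS_LABELS}")

    plots: dict[tuple[str, str], CensusedPlot] = {}
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        key = (row.plot_id, row.census)
        if key not in plots:
            plots[key] = CensusedPlot(
                plot_id=row.plot_id,
                block_id=row.block_id,
                treatment=row.treatment,
                census=row.census,
                window=window,
            )
        if row.species_id == "" and row.x == "" and row.y == "":
            continue  # sentinel row for an empty plot
        try:
            x, y = float(row.x), float(row.y)
        except ValueError as exc:
            raise CensusFormatError(f"row {row_no}: non-numeric coordinate") from exc
        if not window.contains(x, y):
            raise CensusValidationError(
                f"row {row_no}, plot {row.plot_id!r}: ({x}, {y}) outside "
                f"{window.width} x {window.height} window"
            )
        plots[key].individuals.append(IndividualRecord(row.species_id, x, y))

    exp = Experiment(
        plots=[plots[k] for k in sorted(plots)], light_map={k: float(v) for k, v in light_map.items()}
    )
    exp.validate()
    return exp


# ---------------------------------------------------------------------------
# Derivations


def abundance_vector(plot: CensusedPlot) -> Counter:
    """Species -> count map for one plot (empty plot -> empty Counter)."""
    return Counter(ind.species_id for ind in plot.individuals)


def split_into_subplots(
    plot: CensusedPlot, ncols: int = DEFAULT_SUBPLOT_GRID[0], nrows: int = DEFAULT_SUBPLOT_GRID[1]
) -> list[CensusedPlot]:
    """Split a plot into an ncols x nrows grid of equal subplots.

    Cells are half-open ``[x0, x1) x [y0, y1)``, closed on the plot's max
    edges, so every individual lands in exactly one subplot (an individual
    sitting exactly on an interior boundary goes to the higher-index cell).
    Subplot coordinates are re-expressed relative to the subplot origin and
    subplot ids extend the parent id with ``:r<row>c<col>``.
    """
    if ncols < 1 or nrows < 1:
        raise ValueError(f"grid dimensions must be >= 1, got {ncols} x {nrows}")
    cw = plot.window.width / ncols
    ch = plot.window.height / nrows
    sub_window = RectWindow(cw, ch)
    subs = {
        (row, col): CensusedPlot(
            plot_id=f"{plot.plot_id}:r{row}c{col}",
            block_id=plot.block_id,
            treatment=plot.treatment,
            census=plot.census,
            window=sub_window,
        )
        for row in range(nrows)
        for col in range(ncols)
    }
    for ind in plot.individuals:
        col = min(int(ind.x / cw), ncols - 1)
        row = min(int(ind.y / ch), nrows - 1)
        subs[(row, col)].individuals.append(
            IndividualRecord(ind.species_id, ind.x - col * cw, ind.y - row * ch)
        )
    return [subs[(row, col)] for row in range(nrows) for col in range(ncols)]


@dataclass(frozen=True)
class DiversitySummary:
    """Alpha-diversity summary of one abundance vector.

    shannon is in nats; simpson is the Gini–Simpson index 1 - sum p_i^2;
    pielou is H / ln(richness) and NaN when richness == 1 (0/0).
    """

    richness: int
    shannon: float
    simpson: float
    pielou: float


def diversity_indices(counts: Mapping[str, int]) -> DiversitySummary:
    """Richness, Shannon–Wiener (nats), Gini–Simpson and Pielou evenness."""
    from skbio.diversity.alpha import pielou_e, shannon, simpson

    values = np.asarray([c for c in counts.values() if c > 0], dtype=float)
    if values.size == 0 or values.sum() <= 0:
        raise ValueError("diversity indices need at least one individual")
    richness = int(values.size)
    h = float(shannon(values, base=math.e))
    d = float(simpson(values))
    j = float(pielou_e(values)) if richness > 1 else float("nan")
    return DiversitySummary(richness=richness, shannon=h, simpson=d, pielou=j)
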
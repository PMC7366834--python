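"""Figures mirroring the standard result surfaces of a shading experiment."""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def _mpl():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_light_regression(
    pair_records: pd.DataFrame, band: pd.DataFrame, path: str | Path
) -> Path:
    """Scatter of delta_B vs illumination difference with the OLS fit and
    its 95% pointwise confidence band (different-treatment pairs only)."""
    plt = _mpl()
    df = pair_records[pair_records["group"] == "different_treatment"]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(df["light_diff"], df["delta_B"], s=8, alpha=0.3, color="tab:blue")
    ax.plot(band["light_diff"], band["fit"], color="black")
    ax.fill_between(band["light_diff"], band["ci_low"], band["ci_high"], color="grey", alpha=0.4)
    ax.axhline(0.0, ls="--", color="grey")
    ax.set_xlabel("illumination difference (mol m$^{-2}$ d$^{-1}$)")
    ax.set_ylabel(r"$\Delta B$")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_delta_pcf(delta_pcf: pd.DataFrame, path: str | Path) -> Path:
    """One panel per treatment: mean change in relative neighbourhood
    density across replicates with its pointwise band."""
    plt = _mpl()
    treatments = sorted(delta_pcf["treatment"].unique())
    fig, axes = plt.subplots(
        1, len(treatments), figsize=(3.2 * len(treatments), 3.2), sharey=True, squeeze=False
    )
    for ax, treatment in zip(axes[0], treatments):
        sub = delta_pcf[delta_pcf["treatment"] == treatment]
        ax.fill_between(sub["r"], sub["ci_low"], sub["ci_high"], color="grey", alpha=0.5)
        ax.plot(sub["r"], sub["mean_delta"], color="black")
        ax.axhline(0.0, ls="--", color="grey")
        ax.set_title(f"{treatment} shading")
        ax.set_xlabel("r (m)")
    axes[0][0].set_ylabel(r"$\Delta$pcf$(r)$")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
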
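"""Optional figures: dose-response boxplots, count densities, Q-Q plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .popstats import QQResult

__all__ = ["save_count_boxplot", "save_count_density", "save_qq_plot"]


def save_count_boxplot(table: pd.DataFrame, path) -> None:
    """Box-and-whisker plot of per-nucleus focus counts by dose group."""
    doses = sorted(table["dose_nominal_Gy"].unique())
    data = [table.loc[table["dose_nominal_Gy"] == d, "rif_count"].to_numpy() for d in doses]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.boxplot(data, tick_labels=[f"{d:g}" for d in doses], showfliers=False)
    ax.set_xlabel("dose (Gy)")
    ax.set_ylabel("foci per nucleus")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def save_count_density(table: pd.DataFrame, path, normalize: bool = True) -> None:
    """Normalized density of counts per dose group (count / group mean)."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for d in sorted(table["dose_nominal_Gy"].unique()):
        if d == 0:
            continue
        x = table.loc[table["dose_nominal_Gy"] == d, "rif_count"].to_numpy(float)
        if normalize and x.mean() > 0:
            x = x / x.mean()
        ax.hist(x, bins=60, density=True, histtype="step", label=f"{d:g} Gy")
    ax.set_xlabel("normalized foci per nucleus" if normalize else "foci per nucleus")
    ax.set_ylabel("density")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def save_qq_plot(result: QQResult, path, xlabel: str = "specific energy quantile (Gy)",
                 ylabel: str = "focus count quantile") -> None:
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(result.quantiles_x, result.quantiles_y, ".", ms=3, alpha=0.6)
    xs = np.array([result.quantiles_x.min(), result.quantiles_x.max()])
    ax.plot(xs, result.slope * xs + result.intercept, "-", lw=1,
            label=f"slope {result.slope:.2f}, r² {result.r_squared:.3f}")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
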
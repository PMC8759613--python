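"""Headless figure rendering (forest plot, diagnosis bars, predictive check)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .effects import HIGH, LOW, UNDET
from .probit import WEATHER_LABELS


def forest_plot(forest: dict, path) -> None:
    """Caterpillar plot of participant-level intervals, sensitive ones in
    blue, with the population mean as a dotted red reference line."""
    rows: pd.DataFrame = forest["rows"]
    n = len(rows)
    fig, ax = plt.subplots(figsize=(7, 4))
    xs = np.arange(n)
    colors = np.where(rows["label"] == UNDET, "0.7", "tab:blue")
    ax.vlines(xs, rows["lower"], rows["upper"], colors=colors, lw=0.6)
    ax.plot(xs, rows["median"], ".", ms=1.5, color="black")
    ax.axhline(forest["reference"], color="red", ls=":", lw=1.2)
    ax.axhline(0.0, color="0.4", lw=0.6)
    ax.set_xlabel("participants (sorted by posterior median)")
    ax.set_ylabel("total slope (latent scale)")
    ax.set_title(WEATHER_LABELS.get(forest["parameter"], forest["parameter"]))
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def breakdown_bars(breakdown: pd.DataFrame, path) -> None:
    """Low/high-sensitive prevalence per diagnosis group and weather parameter."""
    params = breakdown["parameter"].unique()
    fig, axes = plt.subplots(1, len(params), figsize=(3.2 * len(params), 3.5),
                             sharey=True, squeeze=False)
    for ax, param in zip(axes[0], params):
        sub = breakdown[breakdown["parameter"] == param]
        x = np.arange(len(sub))
        ax.bar(x - 0.2, sub["high_sensitive"], width=0.4, color="gold",
               label="high-value sensitive")
        ax.bar(x + 0.2, sub["low_sensitive"], width=0.4, color="seagreen",
               label="low-value sensitive")
        ax.set_xticks(x)
        ax.set_xticklabels(sub["group"], rotation=30, ha="right", fontsize=7)
        ax.set_title(WEATHER_LABELS.get(param, param), fontsize=8)
    axes[0][0].set_ylabel("prevalence")
    axes[0][0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def ppc_plot(ppc: dict, path) -> None:
    """Observed category frequencies against the replicate predictive band."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    cats = np.arange(1, 6)
    lo, hi = ppc["interval"]
    ax.fill_between(cats, lo, hi, alpha=0.3, color="tab:blue",
                    label="95% predictive band")
    ax.plot(cats, ppc["replicates"].mean(axis=0), "--", color="tab:blue",
            label="replicate mean")
    ax.plot(cats, ppc["observed"], "o-", color="black", label="observed")
    ax.set_xticks(cats)
    ax.set_xlabel("pain category")
    ax.set_ylabel("frequency")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
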
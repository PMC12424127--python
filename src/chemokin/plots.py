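"""Figure helpers; every plot is drawn from an emitted table."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .walks import Trajectory

__all__ = [
    "flower_plot",
    "msd_plot",
    "metric_by_bin_plot",
    "calcium_timecourse_plot",
]


def flower_plot(tracks: list[Trajectory], tip, path) -> None:
    """Trajectory overlay translated so the pipette tip is the origin."""
    fig, ax = plt.subplots(figsize=(5, 5))
    tip = np.asarray(tip, dtype=float)
    for tr in tracks:
        p = tr.positions - tip
        ax.plot(p[:, 0], p[:, 1], lw=0.6, alpha=0.7)
        ax.plot(p[-1, 0], p[-1, 1], ".", ms=2, color="k")
    ax.plot(0, 0, "r+", ms=10)
    ax.set_aspect("equal")
    ax.set_xlabel("x (um, tip at origin)")
    ax.set_ylabel("y (um)")
    fig.savefig(path, dpi=120)
    plt.close(fig)


def msd_plot(msd_by_bin: pd.DataFrame, path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    for b, grp in msd_by_bin.groupby("bin"):
        ax.errorbar(grp["lag_s"], grp["msd_um2"], yerr=grp["sem"],
                    label=f"{b} um", lw=1, capsize=2)
    ax.set_xlabel("lag (s)")
    ax.set_ylabel("MSD (um$^2$)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def metric_by_bin_plot(summary: pd.DataFrame, metric: str, path) -> None:
    df = summary[summary["metric"] == metric]
    fig, ax = plt.subplots(figsize=(4.5, 4))
    x = np.arange(len(df))
    ax.bar(x, df["mean"], yerr=df["sem"].fillna(0), capsize=3)
    ax.set_xticks(x, df["bin"], rotation=45, ha="right")
    ax.set_xlabel("initial distance from tip (um)")
    ax.set_ylabel(metric)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def calcium_timecourse_plot(timecourses: pd.DataFrame, path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    for b, grp in timecourses.groupby("bin"):
        ax.plot(grp["t_s"], grp["mean_drr"], lw=1, label=f"{b} um")
    ax.set_xlabel("time (s)")
    ax.set_ylabel(r"$\Delta$R/R$_0$")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
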
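"""Plotting helpers for run reports (matplotlib, non-interactive backend)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_survival", "plot_coverage", "plot_clone_areas"]


def plot_survival(curves: pd.DataFrame, path) -> Path:
    """Step plot of percent survival per cohort over the observation window."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for cond, sub in curves.groupby("condition"):
        ax.step(sub["day"], sub["percent_survival"], where="post", label=cond)
    ax.set_xlabel("day")
    ax.set_ylabel("% survival")
    ax.set_ylim(0, 105)
    ax.legend(frameon=False)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_coverage(per_image: pd.DataFrame, path, metric: str = "percent_whole") -> Path:
    """Per-condition strip/violin of GFP % coverage."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ok = per_image[per_image["status"] == "ok"]
    conditions = sorted(ok["condition"].unique())
    data = [ok.loc[ok["condition"] == c, metric].dropna() for c in conditions]
    if any(len(d) for d in data):
        ax.violinplot([d.to_numpy() for d in data], showmedians=True)
    ax.set_xticks(range(1, len(conditions) + 1), conditions)
    ax.set_ylabel(f"GFP coverage ({metric}) [%]")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_clone_areas(clones: pd.DataFrame, path, threshold_um2: float = 7800.0) -> Path:
    """Scatter of clone areas per condition with the tumour threshold line."""
    fig, ax = plt.subplots(figsize=(6, 4))
    conditions = sorted(clones["condition"].unique())
    for i, cond in enumerate(conditions):
        areas = clones.loc[clones["condition"] == cond, "area_um2"]
        ax.scatter([i + 1] * len(areas), areas, s=8, alpha=0.5)
    ax.axhline(threshold_um2, linestyle="--", color="grey")
    ax.set_xticks(range(1, len(conditions) + 1), conditions)
    ax.set_ylabel("clone area [um^2]")
    ax.set_yscale("log")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
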
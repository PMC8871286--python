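"""Figure helpers: Bland–Altman plot, ROC curve, change boxplots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .stats import BlandAltmanResult, ROCResult

__all__ = ["plot_bland_altman", "plot_roc", "plot_change_boxplots"]


def plot_bland_altman(a, b, result: BlandAltmanResult, path: str | Path, title: str = "") -> None:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((a + b) / 2.0, a - b, s=14, alpha=0.7)
    for y, style in (
        (result.mean_difference, "-"),
        (result.loa_lower, "--"),
        (result.loa_upper, "--"),
    ):
        ax.axhline(y, color="k", linestyle=style, linewidth=1)
    ax.set_xlabel("mean of methods (%)")
    ax.set_ylabel("difference (%-points)")
    ax.set_title(title or "Bland–Altman")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_roc(result: ROCResult, path: str | Path, title: str = "") -> None:
    pts = np.array([(1.0 - spec, sens) for _, sens, spec in result.operating_points])
    order = np.argsort(pts[:, 0], kind="stable")
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(pts[order, 0], pts[order, 1], "-o", markersize=3)
    ax.plot([0, 1], [0, 1], "k:", linewidth=1)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(title or f"ROC (AUC = {result.auc:.2f}, cutoff = {result.youden_threshold:.2f}%)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_change_boxplots(changes: pd.DataFrame, path: str | Path, title: str = "") -> None:
    """Boxplots of per-subject changes by arm (one panel absolute, one percent)."""
    arms = sorted(changes["arm"].unique())
    fig, axes = plt.subplots(1, 2, figsize=(8, 4))
    for ax, col, label in zip(axes, ("change", "percent_change"), ("%-points", "%")):
        data = [changes.loc[changes["arm"] == arm, col].dropna() for arm in arms]
        ax.boxplot(data, tick_labels=arms)
        ax.axhline(0, color="k", linewidth=0.8, linestyle=":")
        ax.set_ylabel(f"8-week change ({label})")
    fig.suptitle(title or str(changes["measure"].iloc[0]))
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
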
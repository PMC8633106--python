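"""Simple figures: the accumulative coverage curve and method-coverage bars."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .cgfc import CGFCSelection

__all__ = ["plot_coverage_curve", "plot_method_coverage"]


def plot_coverage_curve(selection: CGFCSelection, path, threshold: float | None = None):
    """Cumulative EIS coverage against number of components added."""
    fig, ax = plt.subplots(figsize=(6, 4))
    x = range(1, len(selection.cumulative) + 1)
    ax.step(x, selection.cumulative, where="post")
    if threshold is not None:
        ax.axhline(threshold, linestyle="--", linewidth=0.8, color="grey")
    if selection.selected:
        ax.axvline(len(selection.selected), linestyle=":", linewidth=0.8, color="red")
    ax.set_xlabel("components (best-first)")
    ax.set_ylabel("cumulative EIS coverage")
    ax.set_ylim(0, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_method_coverage(table: pd.DataFrame, path):
    """Bar chart of functional term coverage per node-scoring method."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(table["method"], table["coverage"])
    ax.set_ylabel("reference term coverage")
    ax.set_ylim(0, 1.02)
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
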
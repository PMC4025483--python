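"""Simple figure outputs: eigengene line plots and metabolite box plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .eigengenes import EigenDecomposition
from .metabolomics import MetaboliteTimecourse

__all__ = ["plot_eigengenes", "plot_metabolite_boxes"]


def plot_eigengenes(
    decomp: EigenDecomposition, path: str | Path, top: int = 3
) -> None:
    """Line plot of the leading eigengene temporal patterns."""
    top = min(top, decomp.n_patterns)
    fig, ax = plt.subplots(figsize=(6, 4))
    x = np.arange(len(decomp.stage_labels))
    for i in range(top):
        ax.plot(
            x,
            decomp.eigengenes[i],
            marker="o",
            label=f"pattern {i + 1} (e={decomp.fractions[i]:.2f})",
        )
    ax.set_xticks(x)
    ax.set_xticklabels(decomp.stage_labels, rotation=45, ha="right")
    ax.set_ylabel("eigengene value")
    ax.axhline(0.0, color="grey", lw=0.5)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_metabolite_boxes(
    tc: MetaboliteTimecourse, path: str | Path, metabolites: list[str] | None = None
) -> None:
    """Per-metabolite box plots across timepoints (baseline-relative scale)."""
    mets = metabolites or tc.metabolite_names
    n = len(mets)
    fig, axes = plt.subplots(n, 1, figsize=(7, 2.2 * n), squeeze=False)
    for ax, met in zip(axes[:, 0], mets):
        data = [tc.values_at(met, tp) for tp in tc.timepoint_order]
        data = [d if len(d) else np.array([np.nan]) for d in data]
        ax.boxplot(data, tick_labels=tc.timepoint_order, whis=(0, 100))
        ax.set_title(met, fontsize=9)
        ax.tick_params(axis="x", labelrotation=45, labelsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
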
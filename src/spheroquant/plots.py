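"""Regenerable figures: additivity scatter, cell-cycle bars, ORR heatmaps."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .cellcycle import CellCycleProfile
from .combination import AdditivePrediction, GroupSummary

GROUP_COLORS = {"control": "black", "pdt": "tab:orange", "rt": "tab:blue", "combo": "tab:red"}


def additivity_scatter(
    records: pd.DataFrame,
    groups: dict[str, GroupSummary],
    predicted: AdditivePrediction,
    path: str,
) -> None:
    """Necrosis-vs-area scatter: thin points are spheroids, thick points group
    means +/- SEM, the dashed grey arrow the additive (geometric-sum) prediction."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for name, g in groups.items():
        sel = records[(records.pdt_fluence_J_cm2 == g.pdt_fluence_J_cm2)
                      & (records.rt_dose_Gy == g.rt_dose_Gy)]
        color = GROUP_COLORS.get(name, "gray")
        ax.plot(sel.norm_area, sel.mean_pi, ".", color=color, alpha=0.45, ms=4)
        ax.errorbar(g.mean_norm_area, g.mean_pi, xerr=g.sem_norm_area, yerr=g.sem_pi,
                    fmt="o", color=color, ms=9, capsize=3, label=name)
    c = groups["control"]
    ax.annotate("", xy=(predicted.area, predicted.pi), xytext=(c.mean_norm_area, c.mean_pi),
                arrowprops=dict(arrowstyle="->", color="gray", ls="--"))
    ax.set_xlabel("normalized area")
    ax.set_ylabel("mean PI intensity (background-subtracted)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def cellcycle_bars(profiles: dict[str, CellCycleProfile], path: str) -> None:
    """Stacked-bar summary of phase fractions per condition."""
    names = list(profiles)
    data = np.array([profiles[n].fractions for n in names]) * 100.0
    fig, ax = plt.subplots(figsize=(1.2 * len(names) + 2, 4))
    bottom = np.zeros(len(names))
    for i, (phase, color) in enumerate(
        zip(("sub-G1", "G1", "S", "G2/M"), ("dimgray", "tab:blue", "tab:green", "tab:purple"))
    ):
        ax.bar(names, data[:, i], bottom=bottom, label=phase, color=color)
        bottom += data[:, i]
    ax.set_ylabel("fraction of events (%)")
    ax.legend(fontsize=8)
    plt.setp(ax.get_xticklabels(), rotation=30, ha="right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def orr_heatmap(orr: np.ndarray, path: str) -> None:
    """ORR heatmap on the fixed [0, 1] scale so panels are cross-comparable."""
    fig, ax = plt.subplots(figsize=(4.4, 4))
    im = ax.imshow(orr, vmin=0.0, vmax=1.0, cmap="viridis")
    fig.colorbar(im, ax=ax, label="ORR = FAD / (FAD + NADH)")
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
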
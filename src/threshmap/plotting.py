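"""Benchmark figures: MAPE versus number of sampled electrodes."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .evaluation import BenchmarkResult

__all__ = ["plot_benchmark"]

_KERNEL_COLORS = {"rbf": "tab:blue", "matern15": "tab:orange", "hybrid": "tab:green"}
#: dashed reference error levels drawn on every panel
REFERENCE_LEVELS = (10, 15, 20, 50)


def plot_benchmark(
    result: BenchmarkResult,
    path: str | Path,
    reference_levels: Sequence[float] = REFERENCE_LEVELS,
) -> None:
    """One row per sampling strategy, one column per map; a line per kernel
    with SEM error bars, dashed horizontal reference levels."""
    summ = result.summary(per_map=True)
    strategies = sorted(summ["strategy"].unique())
    maps = sorted(summ["map_label"].unique())
    fig, axes = plt.subplots(
        len(strategies),
        len(maps),
        figsize=(3.2 * len(maps), 2.6 * len(strategies)),
        sharex=True,
        sharey=True,
        squeeze=False,
    )
    for i, strategy in enumerate(strategies):
        for j, label in enumerate(maps):
            ax = axes[i][j]
            cell = summ[(summ["strategy"] == strategy) & (summ["map_label"] == label)]
            for family, sub in cell.groupby("family"):
                sub = sub.sort_values("n_sampled")
                ax.errorbar(
                    sub["n_sampled"],
                    sub["mean_mape"],
                    yerr=sub["sem_mape"],
                    label=family,
                    color=_KERNEL_COLORS.get(family),
                    marker="o",
                    markersize=3,
                    capsize=2,
                )
            for level in reference_levels:
                ax.axhline(level, ls="--", lw=0.6, color="gray", alpha=0.6)
            if i == 0:
                ax.set_title(label, fontsize=9)
            if j == 0:
                ax.set_ylabel(f"{strategy}\nMAPE (%)")
            if i == len(strategies) - 1:
                ax.set_xlabel("sampled electrodes")
    axes[0][0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
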
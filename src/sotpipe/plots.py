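"""Figure generation: Bland-Altman grids and per-condition boxplots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .cop_io import SOT_CONDITIONS


def bland_altman_grid(
    tables: dict[str, pd.DataFrame],
    multiplier: float,
    path: str | Path,
) -> Path:
    """2x3 grid of Bland-Altman plots (eEI minus EI) per SOT condition."""
    fig, axes = plt.subplots(2, 3, figsize=(12, 7), sharex=False)
    for ax, cond in zip(axes.ravel(), SOT_CONDITIONS):
        table = tables.get(cond)
        if table is None or len(table) < 2:
            ax.set_axis_off()
            continue
        x = table["ei"].to_numpy()
        y = table["eei"].to_numpy()
        d = y - x
        mean_pair = (x + y) / 2.0
        md = d.mean()
        sd = d.std(ddof=1)
        ax.scatter(mean_pair, d, s=18, color="0.2")
        ax.axhline(md, color="tab:blue", lw=1.2)
        for lim in (md - multiplier * sd, md + multiplier * sd):
            ax.axhline(lim, color="tab:red", ls="--", lw=1.0)
        ax.set_title(cond)
        ax.set_xlabel("mean of EI and eEI")
        ax.set_ylabel("eEI - EI")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def condition_boxplots(tables: dict[str, pd.DataFrame], path: str | Path) -> Path:
    """Side-by-side EI / eEI boxplots across SOT conditions."""
    fig, ax = plt.subplots(figsize=(10, 5))
    data, positions, colors = [], [], []
    for i, cond in enumerate(SOT_CONDITIONS):
        table = tables.get(cond)
        if table is None or table.empty:
            continue
        data.append(table["ei"].to_numpy())
        positions.append(3 * i)
        colors.append("0.85")
        data.append(table["eei"].to_numpy())
        positions.append(3 * i + 1)
        colors.append("0.45")
    if data:
        boxes = ax.boxplot(data, positions=positions, widths=0.8, patch_artist=True)
        for patch, color in zip(boxes["boxes"], colors):
            patch.set_facecolor(color)
    ax.set_xticks([3 * i + 0.5 for i in range(len(SOT_CONDITIONS))])
    ax.set_xticklabels(SOT_CONDITIONS)
    ax.set_ylabel("equilibrium index score")
    ax.set_title("Equitest EI (light) vs VR eEI (dark) by condition")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
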
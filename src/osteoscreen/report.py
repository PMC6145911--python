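"""Plate heatmaps, rank-plot tables and figure/CSV twins.

Every figure has a machine-readable CSV twin carrying the same numbers, so
screen QC is scriptable and artifacts regenerate deterministically.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .model import N_COLS, N_ROWS, ROW_LETTERS, parse_well
from .stats import GeneResult, HitThresholds

__all__ = ["plate_heatmap", "rank_plot_data", "rank_plot"]

#: Default display scales: cells per well and ALP intensity per cell.
CELL_SCALE = (0.0, 6000.0)
ALP_SCALE = (0.0, 3.75)


def plate_heatmap(
    values: Mapping[str, float],
    scale: tuple[float, float] = CELL_SCALE,
    title: str = "",
    out_png=None,
    out_csv=None,
) -> tuple[plt.Figure, pd.DataFrame]:
    """Render per-well values on the 16x24 grid, clipped at the scale bounds.

    Wells absent from ``values`` are left blank (NaN).  Returns the figure
    and its CSV twin (rows A-P, columns 1-24); both are written when paths
    are given.
    """
    grid = np.full((N_ROWS, N_COLS), np.nan)
    for well, val in values.items():
        row, col = parse_well(well)
        grid[ROW_LETTERS.index(row), col - 1] = val
    frame = pd.DataFrame(grid, index=list(ROW_LETTERS), columns=range(1, N_COLS + 1))

    fig, ax = plt.subplots(figsize=(8, 5))
    shown = np.clip(grid, scale[0], scale[1])
    im = ax.imshow(shown, vmin=scale[0], vmax=scale[1], cmap="viridis", aspect="auto")
    ax.set_xticks(range(N_COLS), labels=[str(c) for c in range(1, N_COLS + 1)], fontsize=6)
    ax.set_yticks(range(N_ROWS), labels=list(ROW_LETTERS), fontsize=6)
    ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.8)
    if out_csv is not None:
        frame.to_csv(out_csv, index_label="row")
    if out_png is not None:
        fig.savefig(out_png, dpi=150)
    return fig, frame


def rank_plot_data(
    results: Sequence[GeneResult],
    statistic: str = "mean_pct_alp",
    thresholds: HitThresholds = HitThresholds(),
) -> pd.DataFrame:
    """Ordered table behind a rank plot, with category color classes.

    ``statistic`` is one of ``mean_pct_cell_number``, ``mean_pct_alp`` or
    ``mean_z_alp``.  Rows are sorted descending by the statistic (ties
    broken by gene symbol, so output is deterministic).  Color classes:
    ``viability`` for cell number < 60% of control; ``up`` for ALP >= 160%
    (inclusive), ``down`` for ALP <= 40%, else ``none``.
    """
    rows = []
    for r in results:
        value = getattr(r, statistic)
        if statistic == "mean_pct_cell_number":
            cls = "viability" if r.mean_pct_cell_number < thresholds.viability_min_pct else "none"
        else:
            if not np.isnan(r.mean_pct_alp) and r.mean_pct_alp >= thresholds.alp_high_pct:
                cls = "up"
            elif not np.isnan(r.mean_pct_alp) and r.mean_pct_alp <= thresholds.alp_low_pct:
                cls = "down"
            else:
                cls = "none"
        rows.append({"gene_symbol": r.gene_symbol, "value": value, "color_class": cls})
    df = pd.DataFrame(rows)
    df = df.sort_values(
        ["value", "gene_symbol"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df


def rank_plot(
    data: pd.DataFrame, title: str = "", out_png=None, out_csv=None
) -> plt.Figure:
    """Scatter the output of :func:`rank_plot_data`."""
    colors = {"none": "0.6", "up": "tab:red", "down": "tab:green", "viability": "tab:cyan"}
    fig, ax = plt.subplots(figsize=(7, 4))
    for cls, grp in data.groupby("color_class"):
        ax.scatter(grp["rank"], grp["value"], s=8, c=colors.get(cls, "k"), label=cls)
    ax.set_xlabel("rank")
    ax.set_ylabel("value")
    ax.set_title(title)
    ax.legend(fontsize=7)
    if out_csv is not None:
        data.to_csv(out_csv, index=False)
    if out_png is not None:
        fig.savefig(out_png, dpi=150)
    return fig
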
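"""One-page cultivar factsheet.

A single matplotlib figure summarising one cultivar: trait statistics table,
average side shape with the per-degree SD band, top-view outline, mean hue
histogram over the informative [0, 0.5] range, and thumbnails of the first
fruit's five views.  The layout is deterministic so regeneration on
unchanged inputs is stable.
"""
from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .classify import AverageShape
from . import color as col
from . import io as fio

__all__ = ["make_factsheet"]


def make_factsheet(cultivar: str, summary: pd.DataFrame,
                   avg_side: AverageShape,
                   mean_hist: col.ColorHistogram,
                   sd_hist: Optional[col.ColorHistogram],
                   out_path, top_profile: Optional[np.ndarray] = None,
                   thumbnail_paths: Optional[Sequence] = None,
                   metadata: Optional[dict] = None) -> Path:
    """Render the factsheet to ``out_path`` (format from the extension)."""
    fig = plt.figure(figsize=(8.27, 11.69))  # A4 portrait
    fig.suptitle(f"Cultivar factsheet: {cultivar}", fontsize=16)

    # trait table
    ax_table = fig.add_axes([0.07, 0.72, 0.86, 0.18])
    ax_table.axis("off")
    cell_text = [[row["trait"], f"{row['n']:d}", f"{row['mean']:.2f}",
                  f"{row['median']:.2f}", f"{row['sd']:.2f}",
                  f"{row['min']:.2f}", f"{row['max']:.2f}"]
                 for _, row in summary.iterrows()]
    table = ax_table.table(
        cellText=cell_text,
        colLabels=["trait", "n", "mean", "median", "sd", "min", "max"],
        loc="center")
    table.scale(1.0, 1.3)

    # average side shape with SD band
    ax_shape = fig.add_axes([0.07, 0.40, 0.40, 0.28])
    theta = np.deg2rad(np.arange(361) % 360)
    mean = np.append(avg_side.mean_radius_deg, avg_side.mean_radius_deg[0])
    sd = np.append(avg_side.sd_radius_deg, avg_side.sd_radius_deg[0])
    ax_shape.plot(mean * np.cos(theta), mean * np.sin(theta), "k-", lw=1.5)
    for sign in (-1.0, 1.0):
        r = mean + sign * sd
        ax_shape.plot(r * np.cos(theta), r * np.sin(theta), "k-", lw=0.5, alpha=0.5)
    ax_shape.set_aspect("equal")
    ax_shape.set_title(f"average side shape (n={avg_side.n_fruit})", fontsize=9)
    ax_shape.set_xlabel("cm", fontsize=8)

    # top outline
    ax_top = fig.add_axes([0.55, 0.40, 0.38, 0.28])
    if top_profile is not None:
        r = np.append(top_profile, top_profile[0])
        ax_top.plot(r * np.cos(theta), r * np.sin(theta), "k-", lw=1.0)
        ax_top.set_aspect("equal")
    ax_top.set_title("top outline (px)", fontsize=9)

    # hue histogram, [0, 0.5] reporting range
    ax_hist = fig.add_axes([0.07, 0.18, 0.86, 0.16])
    centers = 0.5 * (mean_hist.hue_bin_edges[:-1] + mean_hist.hue_bin_edges[1:])
    keep = centers <= 0.5
    width = np.diff(mean_hist.hue_bin_edges).mean()
    colors = plt.cm.hsv(centers[keep])
    ax_hist.bar(centers[keep], mean_hist.hue_density[keep], width=width,
                color=colors, edgecolor="none",
                yerr=None if sd_hist is None else sd_hist.hue_density[keep],
                error_kw={"lw": 0.5})
    ax_hist.set_xlim(0, 0.5)
    ax_hist.set_xlabel("hue (0-1 = 0-360\N{DEGREE SIGN})", fontsize=8)
    ax_hist.set_ylabel("density", fontsize=8)
    ax_hist.set_title("mean hue histogram", fontsize=9)

    # thumbnails of the first fruit
    for i in range(5):
        ax = fig.add_axes([0.07 + i * 0.18, 0.05, 0.16, 0.09])
        ax.axis("off")
        label = f"cam{i + 1}"
        if thumbnail_paths is not None and i < len(thumbnail_paths) \
                and Path(thumbnail_paths[i]).exists():
            image, _ = fio.read_tiff(thumbnail_paths[i])
            small = image[::8, ::8]
            ax.imshow(small / small.max())
        else:
            ax.text(0.5, 0.5, "no image", ha="center", va="center", fontsize=7)
        ax.set_title(label, fontsize=7)

    if metadata:
        text = "  ".join(f"{k}: {v}" for k, v in sorted(metadata.items()))
        fig.text(0.07, 0.015, text, fontsize=7)

    out_path = Path(out_path)
    fig.savefig(out_path, dpi=150, metadata={"Software": "fruitmorph"})
    plt.close(fig)
    return out_path
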
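"""Diagnostic figures: per-subject agreement heatmap and V-H scatter.

The heatmap shows, per subject and zone, how many of the three
repetitions the model classified exactly right (0-3).  The scatter
plots every estimated hand location on the V-H plane with the 4x3 zone
grid overlaid, which makes systematic offsets (e.g. a model clustering
overhead lifts into lower zones) visible at a glance.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .evaluation import AgreementGrid
from .zoning import DEFAULT_BOUNDARIES, ZoneBoundaries

__all__ = ["agreement_heatmap", "vh_scatter"]


def agreement_heatmap(grid: AgreementGrid, path: str | Path, title: str = "") -> Path:
    """Save a subject x zone heatmap of exact-match counts (0-3)."""
    fig, ax = plt.subplots(figsize=(7, 4))
    im = ax.imshow(grid.counts.to_numpy(), cmap="RdYlGn_r", vmin=0, vmax=3,
                   aspect="auto")
    ax.set_xticks(range(12), [str(z) for z in grid.counts.columns])
    ax.set_yticks(range(len(grid.counts.index)), grid.counts.index)
    ax.set_xlabel("lifting zone")
    ax.set_ylabel("subject")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="matching repetitions (of 3)")
    path = Path(path)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path


def vh_scatter(
    results: pd.DataFrame,
    path: str | Path,
    boundaries: ZoneBoundaries = DEFAULT_BOUNDARIES,
    title: str = "",
) -> Path:
    """Save predicted hand locations on the V-H plane with the zone grid.

    ``results`` needs pred_v/pred_h and true_zone columns (the pipeline
    results table); points are coloured by their true zone."""
    det = results[results["detected"]] if "detected" in results.columns else results
    fig, ax = plt.subplots(figsize=(6, 6))
    sc = ax.scatter(det["pred_h"], det["pred_v"], c=det["true_zone"],
                    cmap="tab20", s=14, vmin=1, vmax=12)
    for v in boundaries.v_edges:
        ax.axhline(v, color="0.7", lw=0.8)
    for h in boundaries.h_edges:
        ax.axvline(h, color="0.7", lw=0.8)
    ax.set_xlabel("H: horizontal distance (m)")
    ax.set_ylabel("V: vertical height (m)")
    if title:
        ax.set_title(title)
    fig.colorbar(sc, ax=ax, label="true zone")
    path = Path(path)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path
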
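"""Manhattan plots keyed by pseudochromosome blocks."""

from __future__ import annotations

from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")  # headless, deterministic rendering

import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["manhattan_coords", "make_manhattan"]

# one colour per linkage-group block, cycled in genome order
BLOCK_COLORS = ("#5ab4e5", "#f59b42", "#2b5ba8", "#4daf4a", "#e41a1c")


def manhattan_coords(results: pd.DataFrame) -> tuple[pd.DataFrame, list[int]]:
    """Plot coordinates for an association scan.

    Keeps the scan's genome order; rows without a P-value (flagged
    markers) are dropped.  Returns ``(coords, boundaries)`` where
    ``coords`` has columns ``x`` (cumulative marker index), ``y``
    (−log10 P) and ``chrom``, and ``boundaries`` are the cumulative
    marker counts at the end of each pseudochromosome block.
    """
    if results.empty:
        raise ValueError("empty association results")
    ok = results.dropna(subset=["pvalue"]).reset_index(drop=True)
    if ok.empty:
        raise ValueError("no testable markers in association results")
    coords = pd.DataFrame(
        {
            "x": np.arange(len(ok)),
            "y": -np.log10(ok["pvalue"].to_numpy(dtype=float)),
            "chrom": ok["chrom"].to_numpy(),
        }
    )
    counts = coords.groupby("chrom", sort=False).size()
    boundaries = counts.cumsum().tolist()
    return coords, boundaries


def make_manhattan(
    results: pd.DataFrame,
    path: str | Path | None = None,
    title: str = "",
    threshold: float | None = None,
):
    """Render −log10(P) against cumulative marker index.

    Pseudochromosome blocks are coloured along the X axis; an optional
    significance ``threshold`` draws a horizontal guide.  Returns the
    matplotlib figure (saved to ``path`` when given).
    """
    coords, boundaries = manhattan_coords(results)
    fig, ax = plt.subplots(figsize=(9, 3), dpi=150)
    start = 0
    for i, (chrom, sub) in enumerate(coords.groupby("chrom", sort=False)):
        color = BLOCK_COLORS[i % len(BLOCK_COLORS)]
        ax.scatter(sub["x"], sub["y"], s=6, color=color, linewidths=0)
        end = boundaries[i]
        ax.axvspan(start - 0.5, end - 0.5, ymin=0, ymax=0.02, color=color)
        ax.text((start + end) / 2, -0.02, str(chrom), ha="center", va="top",
                fontsize=7, transform=ax.get_xaxis_transform())
        start = end
    if threshold is not None:
        ax.axhline(-np.log10(threshold), color="grey", lw=0.8, ls="--")
    ax.set_xlabel("marker (genome order)")
    ax.set_ylabel(r"$-\log_{10} P$")
    ax.set_xlim(-0.5, len(coords) - 0.5)
    ax.set_ylim(bottom=0)
    if title:
        ax.set_title(title, fontsize=9)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
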
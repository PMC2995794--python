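"""Genome-wide plots: KC-score overview with threshold lines, two-group
comparative profiles with shaded significant regions, and the scale-space
significance heatmap. Figures are written straight to file via
matplotlib's object API, so no interactive backend is needed."""

from __future__ import annotations

from pathlib import Path

import numpy as np
from matplotlib.figure import Figure

from .compare import ComparativeResult
from .data_model import GenomeLayout, SamplePointGrid
from .recurrent import ScaleSpaceResult, SignificanceResult


def _genome_x(grid: SamplePointGrid) -> np.ndarray:
    offsets = grid.layout.offsets()
    return grid.x + np.array([offsets[c] for c in grid.chrom])


def _chromosome_frame(ax, layout: GenomeLayout) -> None:
    offsets = layout.offsets()
    for name, length in layout:
        ax.axvline(offsets[name], color="0.85", lw=0.8, zorder=0)
        ax.text(offsets[name] + length / 2, 1.01, name, ha="center",
                va="bottom", fontsize=8, transform=ax.get_xaxis_transform())
    ax.set_xlim(0, layout.total_bp)
    ax.set_xlabel("genome position (bp, chromosomes concatenated)")


def genome_plot(gain: SignificanceResult, loss: SignificanceResult,
                path: str | Path) -> None:
    """Gain KC scores plotted upward, loss scores downward, with dashed
    red permutation-threshold lines per channel."""
    grid = gain.profile.grid
    x = _genome_x(grid)
    fig = Figure(figsize=(11, 4))
    ax = fig.subplots()
    ax.plot(x, gain.profile.values, color="tab:blue", lw=0.8, label="gain KC")
    ax.plot(x, -loss.profile.values, color="tab:orange", lw=0.8, label="loss KC")
    ax.axhline(gain.threshold, color="red", ls=":", lw=1.2,
               label=f"threshold (alpha={gain.alpha:g})")
    ax.axhline(-loss.threshold, color="red", ls=":", lw=1.2)
    ax.axhline(0, color="0.5", lw=0.6)
    _chromosome_frame(ax, grid.layout)
    ax.set_ylabel("KC score (gain up / loss down)")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=130)


def compare_plot(result: ComparativeResult, path: str | Path) -> None:
    """Group-mean KC profiles (group 1 red, group 2 black) with significant
    differential regions shaded grey."""
    grid = result.grid
    if grid is None:
        raise ValueError("comparative result has no grid to plot against")
    x = _genome_x(grid)
    offsets = grid.layout.offsets()
    fig = Figure(figsize=(11, 4))
    ax = fig.subplots()
    if result.regions is not None:
        for r in result.regions:
            o = offsets[r.chrom]
            ax.axvspan(o + r.start_bp, o + r.end_bp, color="0.8", zorder=0)
    ax.plot(x, result.mu1, color="red", lw=0.9, label="group 1 mean KC")
    ax.plot(x, result.mu2, color="black", lw=0.9, label="group 2 mean KC")
    _chromosome_frame(ax, grid.layout)
    ax.set_ylabel("mean per-sample KC score")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=130)


def scalespace_plot(ssr: ScaleSpaceResult, path: str | Path) -> None:
    """Heatmap of significance level (-log10 empirical p, gains and losses
    combined) across kernel widths (rows) and genome position (columns);
    non-significant cells are left blank."""
    grid = ssr.grid
    x = _genome_x(grid)
    levels = np.ma.masked_where(ssr.combined_levels() == 0,
                                ssr.combined_levels())
    fig = Figure(figsize=(11, 1.2 + 0.5 * len(ssr.kernel_widths)))
    ax = fig.subplots()
    edges_y = np.arange(len(ssr.kernel_widths) + 1)
    # x is strictly increasing genome-wide, so cell edges are too
    edges_x = np.concatenate([x - grid.spacing / 2, [x[-1] + grid.spacing / 2]])
    mesh = ax.pcolormesh(edges_x, edges_y, levels, cmap="autumn_r",
                         shading="flat")
    ax.set_yticks(edges_y[:-1] + 0.5)
    ax.set_yticklabels([f"{w / 1000:g} kb" for w in ssr.kernel_widths],
                       fontsize=8)
    _chromosome_frame(ax, grid.layout)
    ax.set_ylabel("kernel width")
    fig.colorbar(mesh, ax=ax, label="-log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=130)
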
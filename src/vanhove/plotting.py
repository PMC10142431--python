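"""Rendering of Van Hove grids, peak traces and spectra.

Heatmaps show display-normalized G(r, t) as r-versus-t intensity images
with axes in nm and ps and a colorbar labeled "normalized intensity",
mirroring the standard spatiotemporal-imaging layout for this analysis.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402

from .core import VanHoveGrid, normalize_for_display  # noqa: E402

__all__ = ["render_heatmap", "render_trace", "render_spectrum"]


def render_heatmap(grid: VanHoveGrid, out, *, cmap: str = "jet",
                   title: str | None = None, dpi: int = 150) -> None:
    """Write an r-versus-t intensity image of the grid to ``out``."""
    shown = normalize_for_display(grid)
    fig, ax = plt.subplots(figsize=(6, 4))
    extent = [shown.lags[0], shown.lags[-1],
              shown.r_edges[0], shown.r_edges[-1]]
    im = ax.imshow(shown.values.T, origin="lower", aspect="auto",
                   extent=extent, cmap=cmap, vmin=0.0, vmax=1.0)
    ax.set_xlabel("t (ps)")
    ax.set_ylabel("r (nm)")
    label = {"1D": f"G1D(r,t), axis {grid.axis_or_plane}",
             "2D": f"G2D(r,t), plane {grid.axis_or_plane}",
             "3D": "G3D(r,t)"}[grid.mode]
    ax.set_title(title or label)
    fig.colorbar(im, ax=ax, label="normalized intensity")
    fig.tight_layout()
    fig.savefig(out, dpi=dpi)
    plt.close(fig)


def render_trace(trace, out, *, dpi: int = 150) -> None:
    """Plot first-peak height versus lag."""
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.plot(trace.lags, trace.heights, lw=0.8)
    ax.set_xlabel("t (ps)")
    ax.set_ylabel("first-peak height G")
    ax.set_title(f"peak trace, window {trace.r_window} nm")
    fig.tight_layout()
    fig.savefig(out, dpi=dpi)
    plt.close(fig)


def render_spectrum(spec, out, *, dpi: int = 150) -> None:
    """Plot one-sided power versus frequency (GHz), log power axis."""
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.semilogy(spec.frequencies[1:], spec.power[1:], lw=0.8)
    ax.set_xlabel("f (GHz)")
    ax.set_ylabel("power")
    ax.set_title(f"power spectrum (window={spec.window_name})")
    fig.tight_layout()
    fig.savefig(out, dpi=dpi)
    plt.close(fig)
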
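"""Snapshot rendering of a simulation state.

Three panels mirror the standard presentation of this kind of model: a pH
map on a dark-red-to-yellow scale (low pH dark red, high pH yellow), a cell
map (grey normal tissue, white vessels, dark necrosis, tumour cells
coloured by their glycolytic phenotype) and a macrophage map with each
macrophage coloured by its anti-/pro-tumour mix (blue = CCL2-high
anti-tumour, red = ARG1-high pro-tumour).  Rendering is a pure function of
state: identical states give byte-identical pixel arrays.
"""

from __future__ import annotations

import numpy as np

from . import grid as g

# pH colour stops: dark red -> red -> orange -> yellow
_PH_STOPS = np.array([
    [0.25, 0.0, 0.0],
    [0.65, 0.05, 0.0],
    [1.0, 0.35, 0.0],
    [1.0, 0.85, 0.1],
])

_ANTI_COLOUR = np.array([0.15, 0.35, 0.95])  # CCL2-high, anti-tumour
_PRO_COLOUR = np.array([0.95, 0.15, 0.15])   # ARG1-high, pro-tumour


def _interp_colour(t: np.ndarray, stops: np.ndarray) -> np.ndarray:
    """Piecewise-linear colour interpolation of t in [0,1] over the stops."""
    t = np.clip(t, 0.0, 1.0)
    n = len(stops) - 1
    idx = np.minimum((t * n).astype(int), n - 1)
    frac = t * n - idx
    lo = stops[idx]
    hi = stops[idx + 1]
    return lo + frac[..., None] * (hi - lo)


def render_ph_panel(grid: g.TissueGrid) -> np.ndarray:
    lo, hi = grid.ph_window
    t = (grid.ph() - lo) / (hi - lo)
    return (_interp_colour(t, _PH_STOPS) * 255).astype(np.uint8)


def render_cell_panel(grid: g.TissueGrid, glyc_rate: np.ndarray | None = None,
                      g_max: float = 20.0) -> np.ndarray:
    occ = grid.occupancy
    rgb = np.zeros(occ.shape + (3,))
    rgb[occ == g.EMPTY] = (0.05, 0.05, 0.05)
    rgb[occ == g.NORMAL] = (0.6, 0.6, 0.6)
    rgb[occ == g.VESSEL] = (1.0, 1.0, 1.0)
    rgb[occ == g.NECROTIC] = (0.25, 0.2, 0.15)
    tum = occ == g.TUMOUR
    if np.any(tum):
        if glyc_rate is None:
            t = np.full(int(tum.sum()), 0.5)
        else:
            t = np.clip((glyc_rate[tum] - 1.0) / max(g_max - 1.0, 1e-9), 0, 1)
        # phenotype colouring: low glycolysis teal -> high glycolysis magenta
        rgb[tum] = np.column_stack([0.2 + 0.7 * t, 0.55 - 0.45 * t, 0.45 + 0.4 * t])
    return (rgb * 255).astype(np.uint8)


def render_macrophage_panel(grid: g.TissueGrid, macrophages: list) -> np.ndarray:
    rgb = np.full(grid.shape + (3,), 0.08)
    rgb[grid.vessel_mask] = (0.35, 0.35, 0.35)
    for mac in macrophages:
        t = (mac.behaviour + 1.0) / 2.0
        rgb[mac.position] = (1 - t) * _ANTI_COLOUR + t * _PRO_COLOUR
    return (rgb * 255).astype(np.uint8)


def render_snapshot(
    grid: g.TissueGrid,
    macrophages: list | None = None,
    glyc_rate: np.ndarray | None = None,
    g_max: float = 20.0,
) -> dict:
    """Render the three panels; returns a dict of (H, W, 3) uint8 arrays."""
    return {
        "ph": render_ph_panel(grid),
        "cells": render_cell_panel(grid, glyc_rate, g_max),
        "macrophages": render_macrophage_panel(grid, macrophages or []),
    }


def save_snapshot_figure(panels: dict, path) -> None:
    """Compose the three panels into one figure and save it."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 4))
    for ax, (name, img) in zip(axes, panels.items()):
        ax.imshow(img, interpolation="nearest")
        ax.set_title(name)
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
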
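"""Spatial substrate: tissue lattice, vessels and diffusible fields.

The tissue is a 2D square lattice (one site = one cell diameter, 20 µm by
default).  A handful of sites are blood vessels: Dirichlet boundaries that
supply oxygen and glucose and wash out protons and cytokines.  Each
diffusible quantity lives on its own non-negative scalar field and is
advanced by an explicit forward-time central-space step with reflecting
(no-flux) outer boundaries, followed by reaction (decay towards a baseline)
and a vessel reset.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .errors import ParameterError

#: canonical diffusible field names
FIELD_NAMES = ("oxygen", "glucose", "proton", "pro_cytokine", "anti_cytokine")

# occupancy codes
EMPTY = 0
VESSEL = 1
NORMAL = 2
TUMOUR = 3
NECROTIC = 4

#: neutral (arterial) proton concentration, mol/L, i.e. pH 7.4
H_NEUTRAL = 10.0 ** (-7.4)

#: default physiological clamp applied when converting protons to pH
DEFAULT_PH_WINDOW = (6.0, 7.6)


@dataclass
class FieldParams:
    """Transport/reaction parameters for one diffusible field.

    Parameters
    ----------
    diffusion_coefficient
        Fickian diffusivity, µm²/s.
    decay_rate
        First-order relaxation rate (1/s) towards `baseline` (0 for
        cytokines, the neutral proton concentration for the acid field —
        a lumped description of tissue buffering).
    vessel_value
        Concentration held at vessel sites after every step (Dirichlet).
    baseline
        Value the decay term relaxes towards.
    """

    diffusion_coefficient: float
    decay_rate: float = 0.0
    vessel_value: float = 0.0
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if self.diffusion_coefficient < 0:
            raise ParameterError("diffusion_coefficient must be >= 0")
        if self.decay_rate < 0:
            raise ParameterError("decay_rate must be >= 0")

    def stable_dt(self, dx: float, fraction: float = 0.25) -> float:
        """Largest time step satisfying D*dt/dx^2 <= fraction."""
        if self.diffusion_coefficient == 0:
            return np.inf
        return fraction * dx * dx / self.diffusion_coefficient


@dataclass
class TissueGrid:
    """Lattice of sites with occupancy codes and named scalar fields."""

    width: int
    height: int
    site_spacing: float = 20.0  # µm
    occupancy: np.ndarray = None  # type: ignore[assignment]
    fields: dict = dc_field(default_factory=dict)
    ph_window: tuple = DEFAULT_PH_WINDOW

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ParameterError("grid dimensions must be positive")
        if self.occupancy is None:
            self.occupancy = np.zeros((self.height, self.width), dtype=np.int8)
        if not self.fields:
            self.fields = {name: np.zeros((self.height, self.width)) for name in FIELD_NAMES}

    @property
    def shape(self) -> tuple:
        return (self.height, self.width)

    @property
    def n_sites(self) -> int:
        return self.width * self.height

    @property
    def vessel_mask(self) -> np.ndarray:
        return self.occupancy == VESSEL

    def ph(self) -> np.ndarray:
        """pH map derived from the proton field (clamped)."""
        return proton_to_ph(self.fields["proton"], self.ph_window)


def place_vessels(grid: TissueGrid, density: float, rng_seed: int) -> TissueGrid:
    """Mark ``floor(density * n_sites)`` sites as vessels, uniformly at random.

    Vessel positions are drawn without replacement and are immutable for the
    rest of the run.  Deterministic for a fixed seed.
    """
    if not 0.0 < density < 0.2:
        raise ParameterError(f"vessel density must lie in (0, 0.2), got {density}")
    if np.any(grid.occupancy != EMPTY):
        raise ParameterError("place_vessels requires an empty occupancy grid")
    n_vessels = int(np.floor(density * grid.n_sites))
    rng = np.random.default_rng(rng_seed)
    flat = rng.choice(grid.n_sites, size=n_vessels, replace=False)
    occ = grid.occupancy.ravel()
    occ[flat] = VESSEL
    return grid


def _laplacian(f: np.ndarray) -> np.ndarray:
    """Five-point Laplacian (per dx^2 = 1) with reflecting boundaries.

    Computed as the divergence of inter-site differences over the last two
    axes, so fluxes across the outer boundary are exactly zero (no-flux)
    and the stencil sums to zero — diffusion alone conserves mass.  Works
    on a single field or a stacked (n_fields, H, W) array.
    """
    lap = np.zeros_like(f)
    d = np.diff(f, axis=-2)
    lap[..., :-1, :] += d
    lap[..., 1:, :] -= d
    d = np.diff(f, axis=-1)
    lap[..., :, :-1] += d
    lap[..., :, 1:] -= d
    return lap


def diffuse_react(
    field: np.ndarray,
    params: FieldParams,
    sources: np.ndarray | float,
    sinks: np.ndarray | float,
    dt: float,
    dx: float = 20.0,
    vessel_mask: np.ndarray | None = None,
) -> np.ndarray:
    """One explicit diffusion-reaction step.

    Operator-split update: diffuse, then react (sources − sinks − decay
    towards the baseline), then reset vessel sites to ``vessel_value``.
    The result is clipped at zero.  Raises on a violated stability
    criterion (``D*dt/dx^2 > 0.25``) or mismatched shapes.
    """
    if dt <= 0:
        raise ParameterError("dt must be positive")
    nu = params.diffusion_coefficient * dt / (dx * dx)
    if nu > 0.25 + 1e-12:
        raise ParameterError(
            f"explicit-scheme stability violated: D*dt/dx^2 = {nu:.3g} > 0.25"
        )
    sources = np.asarray(sources, dtype=float)
    sinks = np.asarray(sinks, dtype=float)
    for arr, nm in ((sources, "sources"), (sinks, "sinks")):
        if arr.ndim and arr.shape != field.shape:
            raise ParameterError(f"{nm} shape {arr.shape} does not match field {field.shape}")
    out = field + nu * _laplacian(field)
    out += dt * (sources - sinks)
    if params.decay_rate > 0:
        out -= dt * params.decay_rate * (out - params.baseline)
    np.clip(out, 0.0, None, out=out)
    if vessel_mask is not None:
        out[vessel_mask] = params.vessel_value
    return out


def export_fields(grid: TissueGrid, run_id: str, t: float, out_dir) -> list:
    """Dump every field as a plain CSV matrix, one file per field.

    Files follow the pattern ``{run_id}_{field}_{t}.csv``; returns the
    written paths.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, f in grid.fields.items():
        p = out / f"{run_id}_{name}_{t:g}.csv"
        np.savetxt(p, f, delimiter=",")
        paths.append(p)
    return paths


def proton_to_ph(
    proton_field: np.ndarray | float,
    window: tuple = DEFAULT_PH_WINDOW,
) -> np.ndarray:
    """Convert a proton concentration field (mol/L) to a clamped pH map.

    pH = −log10[H+]; zero concentrations map to the upper clamp.  The map is
    antitone in the proton concentration.
    """
    h = np.asarray(proton_field, dtype=float)
    if np.any(h < 0):
        raise ParameterError("proton concentrations must be non-negative")
    lo, hi = window
    with np.errstate(divide="ignore"):
        ph = np.where(h > 0, -np.log10(np.maximum(h, 1e-300)), hi)
    return np.clip(ph, lo, hi)
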
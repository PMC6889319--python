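"""Tumour and normal cell agents: metabolism, fate and takeover.

Cells occupy lattice sites and couple to the oxygen, glucose and proton
fields.  Tumour cells carry two heritable traits — a glycolytic-rate
multiplier (Warburg phenotype) and an acid-resistance pH threshold — that
mutate at division, so acid-mediated selection emerges from the dynamics
rather than being imposed.  Normal cells metabolise at baseline, do not
mutate, and die under the same ATP and pH rules, providing the tissue the
tumour invades.

ATP stoichiometry follows the usual hybrid-CA convention of ~29 ATP per
glucose oxidised versus 2 ATP per glucose fermented; fermentation exports
protons in proportion to glycolytic flux, which is what acidifies the
microenvironment.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np

from . import grid as g
from .errors import ParameterError

VIABLE = "viable"
QUIESCENT = "quiescent"
NECROTIC = "necrotic"

_STATES = (VIABLE, QUIESCENT, NECROTIC)


@dataclass
class MetabolismParams:
    """Metabolic and fate parameters shared by normal and tumour cells.

    Fluxes are expressed relative to the baseline oxidative glucose flux of
    a normal cell at substrate saturation (dimensionless); ATP is reported
    in the same relative units (a fully oxidative cell at saturation yields
    29 + 2 = 31).  Field drawdown uses normalised concentration units in
    which the vessel value of oxygen and glucose is 1.
    """

    ox_flux_max: float = 1.0          # maximal oxidative glucose flux (relative)
    gly_flux_base: float = 1.0        # baseline glycolytic flux multiplier
    atp_per_ox: float = 29.0          # ATP per unit oxidative flux
    atp_per_gly: float = 2.0          # ATP per unit glycolytic flux
    k_oxygen: float = 0.3             # Monod constant, oxygen (vessel units)
    k_glucose: float = 0.3            # Monod constant, glucose (vessel units)
    oxygen_per_ox: float = 0.12       # O2 drawdown per unit oxidative flux (conc/h)
    glucose_per_flux: float = 0.004   # glucose drawdown per unit total flux (conc/h)
    proton_per_gly: float = 1e-8      # proton export, mol/L per unit gly flux per h
    atp_death: float = 6.0            # below: necrosis
    atp_quiescence: float = 12.0      # below: division clock frozen
    acid_death_prob: float = 0.3      # per-hour death probability below resistance
    necrotic_lysis_prob: float = 0.02  # per-hour chance a necrotic site dissolves
    normal_turnover_prob: float = 0.002  # per-hour apoptotic turnover of normal cells
    division_time: float = 24.0       # h between divisions at full ATP
    g_max: float = 40.0               # upper bound on glycolytic-rate multiplier
    mutation_prob: float = 0.1        # per trait per division
    gly_mutation_step: float = 0.5
    acid_mutation_step: float = 0.05
    acid_resistance_bounds: tuple = (6.0, 7.1)
    normal_acid_threshold: float = 6.9  # acid-resistance of normal cells

    def __post_init__(self) -> None:
        for name in (
            "ox_flux_max", "gly_flux_base", "atp_per_ox", "atp_per_gly",
            "k_oxygen", "k_glucose", "oxygen_per_ox", "glucose_per_flux",
            "proton_per_gly", "atp_death", "division_time",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.atp_quiescence <= self.atp_death:
            raise ParameterError("atp_quiescence must exceed atp_death")
        if not 0 <= self.mutation_prob <= 1:
            raise ParameterError("mutation_prob must lie in [0, 1]")


@dataclass
class TumourCell:
    """A single tumour (or normal) cell agent.

    ``glycolytic_rate`` is a dimensionless multiplier (>= 1) of the baseline
    glycolytic flux; ``acid_resistance`` is the pH below which the cell is
    at risk of acid-induced death.
    """

    position: tuple
    glycolytic_rate: float = 1.0
    acid_resistance: float = 6.6
    state: str = VIABLE
    age_since_division: float = 0.0
    is_tumour: bool = True

    def __post_init__(self) -> None:
        if self.state not in _STATES:
            raise ParameterError(f"unknown cell state {self.state!r}")
        if self.glycolytic_rate < 1.0:
            raise ParameterError("glycolytic_rate must be >= 1")


def metabolise(
    cell: TumourCell,
    local_glucose: float,
    local_oxygen: float,
    params: MetabolismParams,
    dt: float = 1.0,
) -> tuple:
    """Metabolic fluxes of one cell given local substrate concentrations.

    Returns ``(atp_rate, glucose_consumed, oxygen_consumed, protons_produced)``.
    Oxidative flux is limited by local oxygen, glycolytic flux equals
    ``glycolytic_rate x baseline`` limited by local glucose (Monod kinetics
    in both substrates), and consumption is additionally capped so it never
    exceeds the locally available amount over ``dt``.
    """
    if cell.state == NECROTIC:
        raise ParameterError("necrotic cells do not metabolise")
    if local_glucose < 0 or local_oxygen < 0:
        raise ParameterError("local concentrations must be >= 0")
    f_o = local_oxygen / (local_oxygen + params.k_oxygen) if local_oxygen > 0 else 0.0
    f_g = local_glucose / (local_glucose + params.k_glucose) if local_glucose > 0 else 0.0
    rate = cell.glycolytic_rate if cell.is_tumour else 1.0
    ox = params.ox_flux_max * f_o * f_g
    gly = params.gly_flux_base * rate * f_g
    atp_rate = params.atp_per_ox * ox + params.atp_per_gly * gly
    glucose_consumed = min(params.glucose_per_flux * (ox + gly) * dt, local_glucose)
    oxygen_consumed = min(params.oxygen_per_ox * ox * dt, local_oxygen)
    protons_produced = params.proton_per_gly * gly * dt
    return atp_rate, glucose_consumed, oxygen_consumed, protons_produced


def mutate_traits(
    glycolytic_rate: float,
    acid_resistance: float,
    params: MetabolismParams,
    rng: np.random.Generator,
) -> tuple:
    """Perturb each heritable trait by ± its step with mutation probability."""
    if rng.random() < params.mutation_prob:
        glycolytic_rate += params.gly_mutation_step * (1 if rng.random() < 0.5 else -1)
    if rng.random() < params.mutation_prob:
        acid_resistance += params.acid_mutation_step * (1 if rng.random() < 0.5 else -1)
    lo, hi = params.acid_resistance_bounds
    return (
        float(np.clip(glycolytic_rate, 1.0, params.g_max)),
        float(np.clip(acid_resistance, lo, hi)),
    )


def update_fate(
    cell: TumourCell,
    atp_rate: float,
    local_ph: float,
    dt: float,
    rng: np.random.Generator,
    params: MetabolismParams,
    free_site: Optional[tuple] = None,
) -> Optional[TumourCell]:
    """Advance one cell's state for ``dt`` hours; return a daughter if it divides.

    Order of checks: ATP starvation -> necrosis; acidosis below the cell's
    resistance threshold -> stochastic death; intermediate ATP -> quiescence
    (division clock frozen); otherwise the clock advances and, on maturity,
    the cell divides into ``free_site`` if one is offered.  Necrotic cells
    persist on the lattice until phagocytosed.
    """
    if dt <= 0:
        raise ParameterError("dt must be positive")
    if cell.state == NECROTIC:
        return None
    threshold = cell.acid_resistance if cell.is_tumour else params.normal_acid_threshold
    if atp_rate < params.atp_death:
        cell.state = NECROTIC
        return None
    if local_ph < threshold and rng.random() < params.acid_death_prob * dt:
        cell.state = NECROTIC
        return None
    if atp_rate < params.atp_quiescence:
        cell.state = QUIESCENT
        return None
    cell.state = VIABLE
    cell.age_since_division += dt
    if cell.age_since_division >= params.division_time and free_site is not None:
        cell.age_since_division = 0.0
        if cell.is_tumour:
            g_rate, a_res = mutate_traits(
                cell.glycolytic_rate, cell.acid_resistance, params, rng
            )
        else:
            g_rate, a_res = cell.glycolytic_rate, cell.acid_resistance
        return TumourCell(
            position=free_site,
            glycolytic_rate=g_rate,
            acid_resistance=a_res,
            is_tumour=cell.is_tumour,
        )
    return None


def takeover_fraction(
    occupancy: np.ndarray,
    tumour_mask: np.ndarray | None = None,
) -> float:
    """Fraction of non-vessel sites occupied by viable tumour cells.

    ``occupancy`` uses the codes from :mod:`acidmac.grid`.  Necrotic sites
    do not count as tumour; quiescent tumour cells are alive and do.
    """
    non_vessel = int(np.sum(occupancy != g.VESSEL))
    if non_vessel == 0:
        return 0.0
    if tumour_mask is None:
        tumour_mask = occupancy == g.TUMOUR
    return float(np.sum(tumour_mask)) / non_vessel
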
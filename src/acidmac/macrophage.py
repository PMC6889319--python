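"""Macrophage agents with a continuous, environment-driven phenotype.

Each macrophage carries a behaviour scalar in [-1, 1] (-1 = extreme
anti-tumour / M1-like, +1 = extreme pro-tumour / M2-like).  Every step the
agent reads its local milieu — extracellular pH, pro- and anti-inflammatory
cytokine concentrations, and the tumour and necrotic cells it is currently
digesting — and re-evaluates a set of calibrated per-gene linear models

    y_i = alpha_i + beta_i * p + gamma_i * e + delta_i * p * e

where ``p`` is the pH the macrophage responds to and ``e`` is an ecological
variable summarising the milieu,

    e = -0.5*a - 0.5*b + 0.5*c + 0.5*d

with a = normalised pro-inflammatory cytokine level, b = fraction of
digestion capacity holding tumour cells, c = normalised anti-inflammatory
cytokine level, d = fraction holding necrotic cells.  e = -1 is the extreme
inflammatory, tumour-rich milieu; e = +1 the anti-inflammatory, necrotic
one.

The two-scenario experiment hinges on ``effective_ph``: pH-sensitive
macrophages respond to the true local pH, pH-insensitive ones behave as if
the pH were always 7.4.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from . import grid as g
from .errors import ConfigurationError, ParameterError

logger = logging.getLogger(__name__)

ANTI_TUMOUR = "anti_tumour"
PRO_TUMOUR = "pro_tumour"

SENSITIVE = "sensitive"
INSENSITIVE = "insensitive"

# digestion-queue item kinds
QUEUE_TUMOUR = "tumour"
QUEUE_NECROTIC = "necrotic"


@dataclass
class EcologicalState:
    """Normalised milieu signals and the derived ecological variable."""

    a: float = 0.0  # pro-inflammatory cytokine, normalised to [0, 1]
    b: float = 0.0  # tumour cells being digested / capacity
    c: float = 0.0  # anti-inflammatory cytokine, normalised to [0, 1]
    d: float = 0.0  # necrotic cells being digested / capacity
    e: float = 0.0


@dataclass
class TraitModel:
    """Fitted linear model for one gene trait, plus normalisation metadata."""

    name: str
    polarity: str  # anti_tumour or pro_tumour
    alpha: float
    beta: float
    gamma: float
    delta: float
    ref_min: float = 0.0
    ref_max: float = 1.0

    def __post_init__(self) -> None:
        if self.polarity not in (ANTI_TUMOUR, PRO_TUMOUR):
            raise ConfigurationError(
                f"trait {self.name!r}: polarity must be "
                f"'{ANTI_TUMOUR}' or '{PRO_TUMOUR}', got {self.polarity!r}"
            )
        for coef in ("alpha", "beta", "gamma", "delta"):
            if not np.isfinite(getattr(self, coef)):
                raise ConfigurationError(f"trait {self.name!r}: {coef} is not finite")
        if self.ref_max <= self.ref_min:
            raise ConfigurationError(f"trait {self.name!r}: ref_max must exceed ref_min")

    def predict(self, p: float, e: float):
        return self.alpha + self.beta * p + self.gamma * e + self.delta * p * e

    def normalise(self, y: float):
        return np.clip((y - self.ref_min) / (self.ref_max - self.ref_min), 0.0, 1.0)


class PhenotypeModel:
    """Collection of calibrated trait models mapping (pH, e) to behaviour."""

    COLUMNS = ["trait", "polarity", "alpha", "beta", "gamma", "delta", "ref_min", "ref_max"]

    def __init__(self, traits: list[TraitModel]):
        if not traits:
            raise ConfigurationError("PhenotypeModel requires at least one trait")
        self.traits = {t.name: t for t in traits}

    def __contains__(self, name: str) -> bool:
        return name in self.traits

    def trait_names(self) -> list[str]:
        return list(self.traits)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "PhenotypeModel":
        missing = [c for c in cls.COLUMNS if c not in df.columns]
        if missing:
            raise ConfigurationError(f"coefficient table missing columns {missing}")
        return cls([TraitModel(
            name=row.trait, polarity=row.polarity,
            alpha=float(row.alpha), beta=float(row.beta),
            gamma=float(row.gamma), delta=float(row.delta),
            ref_min=float(row.ref_min), ref_max=float(row.ref_max),
        ) for row in df.itertuples()])

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            [t.name, t.polarity, t.alpha, t.beta, t.gamma, t.delta, t.ref_min, t.ref_max]
            for t in self.traits.values()
        ]
        return pd.DataFrame(rows, columns=self.COLUMNS)


@dataclass
class MacrophageParams:
    """Behavioural parameters of the macrophage population."""

    count_fraction: float = 0.04   # macrophages per lattice site
    p_kill: float = 1.0            # max per-hour tumour-engulfment probability
    p_clear: float = 1.0           # max per-hour necrotic-clearance probability
    capacity: int = 4              # digestion-queue size
    digestion_time: float = 6.0    # h to digest one engulfed cell
    s_pro: float = 0.5             # max pro-inflammatory secretion (conc/h)
    s_anti: float = 0.5            # max anti-inflammatory secretion (conc/h)
    p_move: float = 0.7            # per-hour probability of a random-walk step
    k_half_pro: float = 0.3        # half-saturation for cytokine normalisation
    k_half_anti: float = 0.3

    def __post_init__(self) -> None:
        for name in ("p_kill", "p_clear", "p_move"):
            if not 0 <= getattr(self, name) <= 1:
                raise ParameterError(f"{name} must lie in [0, 1]")
        if self.capacity < 1:
            raise ParameterError("capacity must be >= 1")
        if not 0 <= self.count_fraction < 1:
            raise ParameterError("count_fraction must lie in [0, 1)")


@dataclass
class Macrophage:
    """One macrophage agent."""

    position: tuple
    eco: EcologicalState = dc_field(default_factory=EcologicalState)
    expression: dict = dc_field(default_factory=dict)
    behaviour: float = 0.0
    digestion_queue: list = dc_field(default_factory=list)  # [kind, remaining_h]
    digested_count: int = 0

    def queue_count(self, kind: str) -> int:
        return sum(1 for item in self.digestion_queue if item[0] == kind)


def ecological_variable(a: float, b: float, c: float, d: float) -> float:
    """Ecological variable e = -0.5a - 0.5b + 0.5c + 0.5d, bounded in [-1, 1].

    Inputs must already be normalised to [0, 1]; a and b pull towards the
    inflammatory/anti-tumour pole, c and d towards the anti-inflammatory/
    pro-tumour pole.
    """
    for name, v in (("a", a), ("b", b), ("c", c), ("d", d)):
        if not 0.0 <= v <= 1.0:
            raise ParameterError(f"ecological input {name}={v} outside [0, 1]")
    return -0.5 * a - 0.5 * b + 0.5 * c + 0.5 * d


def trait_expression(model: PhenotypeModel, trait: str, p: float, e: float) -> float:
    """Predicted expression of one trait at pH ``p`` and ecology ``e``."""
    if trait not in model.traits:
        raise KeyError(f"unknown trait {trait!r}")
    return float(model.traits[trait].predict(p, e))


def effective_ph(local_ph: float, scenario: str) -> float:
    """pH a macrophage responds to: the local value, or 7.4 if pH-insensitive."""
    if scenario == SENSITIVE:
        return local_ph
    if scenario == INSENSITIVE:
        return 7.4
    raise ParameterError(f"unknown scenario {scenario!r}")


def behaviour_from_expression(model: PhenotypeModel, expression: dict) -> float:
    """Map per-trait expression to the behaviour scalar.

    Each trait is min-max normalised by its reference range (clipped to
    [0, 1]); behaviour = mean(normalised pro-tumour traits) − mean(normalised
    anti-tumour traits), clipped to [-1, 1].
    """
    pro, anti = [], []
    for name, y in expression.items():
        t = model.traits[name]
        (pro if t.polarity == PRO_TUMOUR else anti).append(t.normalise(y))
    score = (np.mean(pro) if pro else 0.0) - (np.mean(anti) if anti else 0.0)
    return float(np.clip(score, -1.0, 1.0))


def update_behaviour(
    mac: Macrophage,
    model: PhenotypeModel,
    local_ph: float,
    local_pro_cytokine: float,
    local_anti_cytokine: float,
    scenario: str,
    params: MacrophageParams,
) -> Macrophage:
    """Recompute the ecological state, trait expression and behaviour scalar.

    Cytokine concentrations are normalised to [0, 1] with Michaelis-type
    half-saturation; b and d are current digestion-queue occupancy
    fractions.
    """
    a = local_pro_cytokine / (local_pro_cytokine + params.k_half_pro)
    c = local_anti_cytokine / (local_anti_cytokine + params.k_half_anti)
    b = mac.queue_count(QUEUE_TUMOUR) / params.capacity
    d = mac.queue_count(QUEUE_NECROTIC) / params.capacity
    e = ecological_variable(a, b, c, d)
    mac.eco = EcologicalState(a=a, b=b, c=c, d=d, e=e)
    p = effective_ph(local_ph, scenario)
    mac.expression = {name: trait_expression(model, name, p, e) for name in model.traits}
    mac.behaviour = behaviour_from_expression(model, mac.expression)
    return mac


def _neighbours(pos: tuple, shape: tuple) -> list:
    r, c = pos
    out = []
    if r > 0:
        out.append((r - 1, c))
    if r < shape[0] - 1:
        out.append((r + 1, c))
    if c > 0:
        out.append((r, c - 1))
    if c < shape[1] - 1:
        out.append((r, c + 1))
    return out


def act(
    mac: Macrophage,
    occupancy: np.ndarray,
    mac_occupancy: np.ndarray,
    fields: dict,
    params: MacrophageParams,
    rng: np.random.Generator,
    dt: float = 1.0,
) -> dict:
    """Apply one step of macrophage actions to the lattice.

    In order: (i) digestion timers advance and completed digestions leave
    the queue; (ii) phagocytosis — with probability ``p_kill*max(0, -behaviour)``
    engulf one adjacent viable tumour cell, with probability
    ``p_clear*max(0, +behaviour)`` engulf one adjacent necrotic cell (queue
    bounded by capacity); (iii) secretion of pro-/anti-inflammatory cytokine
    at the macrophage's own site at rates scaled by the matching behaviour
    half; (iv) movement — a uniformly random free von-Neumann neighbour with
    probability ``p_move``, except that an engaged macrophage (non-empty
    digestion queue or an adjacent target of its preferred kind) stays put,
    mimicking contact retention during phagocytosis.

    Returns an action summary dict (engulfed/digested counts, moved flag).
    """
    summary = {"engulfed_tumour": 0, "engulfed_necrotic": 0, "digested": 0, "moved": False}
    # (i) digestion progress
    for item in mac.digestion_queue:
        item[1] -= dt
    done = [item for item in mac.digestion_queue if item[1] <= 0]
    if done:
        mac.digestion_queue = [item for item in mac.digestion_queue if item[1] > 0]
        mac.digested_count += len(done)
        summary["digested"] = len(done)

    nbrs = _neighbours(mac.position, occupancy.shape)
    rng.shuffle(nbrs)
    # (ii) phagocytosis
    if len(mac.digestion_queue) < params.capacity:
        p_tum = params.p_kill * max(0.0, -mac.behaviour)
        p_nec = params.p_clear * max(0.0, mac.behaviour)
        if p_tum > 0 and rng.random() < p_tum:
            for pos in nbrs:
                if occupancy[pos] == g.TUMOUR:
                    occupancy[pos] = g.EMPTY
                    mac.digestion_queue.append([QUEUE_TUMOUR, params.digestion_time])
                    summary["engulfed_tumour"] = 1
                    break
        if (
            len(mac.digestion_queue) < params.capacity
            and p_nec > 0
            and rng.random() < p_nec
        ):
            for pos in nbrs:
                if occupancy[pos] == g.NECROTIC:
                    occupancy[pos] = g.EMPTY
                    mac.digestion_queue.append([QUEUE_NECROTIC, params.digestion_time])
                    summary["engulfed_necrotic"] = 1
                    break
    # (iii) secretion at own site
    fields["pro_cytokine"][mac.position] += params.s_pro * max(0.0, -mac.behaviour) * dt
    fields["anti_cytokine"][mac.position] += params.s_anti * max(0.0, mac.behaviour) * dt
    # (iv) movement with contact retention
    engaged = bool(mac.digestion_queue)
    if not engaged:
        target = g.TUMOUR if mac.behaviour < 0 else g.NECROTIC
        engaged = any(occupancy[pos] == target for pos in nbrs)
    if not engaged and rng.random() < params.p_move:
        # macrophages are interstitial: they may share a site with a normal
        # cell but not with tumour, necrosis, a vessel or another macrophage
        free = [
            pos for pos in nbrs
            if occupancy[pos] in (g.EMPTY, g.NORMAL) and not mac_occupancy[pos]
        ]
        if free:
            new = free[rng.integers(len(free))]
            mac_occupancy[mac.position] = False
            mac_occupancy[new] = True
            mac.position = new
            summary["moved"] = True
    return summary


def maintain_population(
    occupancy: np.ndarray,
    mac_occupancy: np.ndarray,
    macrophages: list,
    target_count: int,
    rng: np.random.Generator,
) -> list:
    """Top the population up to ``target_count`` with naive macrophages.

    Recruits (behaviour 0, empty queue) extravasate at random free sites
    adjacent to vessels.  Macrophages neither die nor divide in-model, so a
    surplus cannot arise.  If too few free perivascular sites exist the
    deficit is logged and the count falls short.
    """
    if target_count < 0:
        raise ParameterError("target_count must be >= 0")
    deficit = target_count - len(macrophages)
    if deficit <= 0:
        return macrophages
    vessel = occupancy == g.VESSEL
    near_vessel = np.zeros_like(vessel)
    near_vessel[:-1, :] |= vessel[1:, :]
    near_vessel[1:, :] |= vessel[:-1, :]
    near_vessel[:, :-1] |= vessel[:, 1:]
    near_vessel[:, 1:] |= vessel[:, :-1]
    free = (occupancy == g.EMPTY) | (occupancy == g.NORMAL)
    candidates = np.argwhere(near_vessel & free & ~mac_occupancy)
    if len(candidates) < deficit:
        logger.warning(
            "macrophage recruitment short: %d free perivascular sites for %d recruits",
            len(candidates), deficit,
        )
    n_place = min(deficit, len(candidates))
    if n_place > 0:
        idx = rng.choice(len(candidates), size=n_place, replace=False)
        for i in idx:
            pos = tuple(int(v) for v in candidates[i])
            mac_occupancy[pos] = True
            macrophages.append(Macrophage(position=pos))
    return macrophages
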
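"""The hybrid simulation engine coupling fields, cells and macrophages.

One cell step represents one hour of simulated time.  Each step:

1. metabolic source/sink rates are computed for every live cell from the
   current oxygen and glucose fields (vectorised mirror of
   :func:`acidmac.tumour.metabolise`);
2. the diffusible fields are relaxed by several explicit sub-steps with
   those rates held fixed (diffuse, react, vessel reset);
3. cell fates are updated from the resulting ATP and pH (necrosis, acid
   death, quiescence, division with heritable mutation);
4. each macrophage re-evaluates its phenotype from its local milieu and
   acts (phagocytosis, secretion, movement);
5. the macrophage population is topped up to its constant target.

Because the physical diffusivities of small metabolites are orders of
magnitude too fast to resolve explicitly on an hourly clock, the engine
rescales all diffusion coefficients by a single factor so the fastest field
sits at the configured stability fraction per sub-step.  This treats the
sub-step loop as a relaxation towards the quasi-steady field profile while
preserving the relative speeds of the diffusibles; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from . import grid as g
from . import macrophage as mac_mod
from . import tumour as tum_mod
from .calibration import default_true_model
from .config import RunConfig
from .errors import SimulationError
from .grid import FieldParams, TissueGrid, place_vessels
from .macrophage import Macrophage, PhenotypeModel

_FINITE_CHECK_INTERVAL = 100  # steps between non-finite field checks


@dataclass
class StepStats:
    """Per-step aggregate record used for trajectories and event logs."""

    time: float
    n_tumour: int
    n_normal: int
    n_necrotic: int
    takeover: float
    min_ph: float
    mean_behaviour: float
    divisions: int
    acid_deaths: int
    atp_necroses: int
    phagocytosed: int


@dataclass
class Trajectory:
    records: list = dc_field(default_factory=list)

    def append(self, stats: StepStats) -> None:
        self.records.append(stats)

    def as_rows(self) -> list:
        return [vars(r) for r in self.records]


class Simulation:
    """One replicate of the tumour–macrophage model."""

    def __init__(
        self,
        config: RunConfig,
        scenario: str,
        seed: int,
        phenotype_model: PhenotypeModel | None = None,
    ):
        self.config = config
        self.scenario = scenario
        self.rng = np.random.default_rng(seed)
        self.model = phenotype_model or default_true_model()
        self.params = config.metabolism_params()
        self.mac_params = config.macrophage_params()

        grd = config.section("grid")
        self.grid = TissueGrid(
            width=int(grd["width"]), height=int(grd["height"]),
            site_spacing=grd["site_spacing"],
            ph_window=(grd["ph_min"], grd["ph_max"]),
        )
        place_vessels(self.grid, grd["vessel_density"],
                      rng_seed=int(self.rng.integers(2**31)))
        shape = self.grid.shape
        occ = self.grid.occupancy
        occ[occ == g.EMPTY] = g.NORMAL

        # per-site heritable traits and division clocks
        tum = config.section("tumour")
        self.glyc_rate = np.ones(shape)
        self.acid_res = np.full(shape, self.params.normal_acid_threshold)
        # stagger division clocks so the tissue does not divide in lockstep
        self.age = self.rng.uniform(0.0, self.params.division_time, shape)
        self.quiescent = np.zeros(shape, dtype=bool)
        self._seed_tumour(int(tum["initial_cluster_size"]),
                          tum["initial_glycolytic_rate"],
                          tum["initial_acid_resistance"])

        # fields start at their vessel-supplied values (cytokines at zero)
        fp = {name: FieldParams(**config.section("fields")[name]) for name in g.FIELD_NAMES}
        num = config.section("numerics")
        self.substeps = int(num["substeps_per_step"])
        self.dt_sub = 3600.0 / self.substeps  # seconds per field sub-step
        dx = self.grid.site_spacing
        d_max = max(p.diffusion_coefficient for p in fp.values())
        scale = 1.0
        if d_max > 0:
            stable = num["stability_fraction"] * dx * dx / self.dt_sub
            scale = min(1.0, stable / d_max)
        self.field_params = {
            name: FieldParams(
                diffusion_coefficient=p.diffusion_coefficient * scale,
                decay_rate=p.decay_rate, vessel_value=p.vessel_value,
                baseline=p.baseline,
            )
            for name, p in fp.items()
        }
        for name in ("oxygen", "glucose", "proton"):
            self.grid.fields[name][:] = self.field_params[name].vessel_value

        # stacked per-field constants for the fast relaxation loop
        dxx = dx * dx
        self._nu = np.array([
            self.field_params[n].diffusion_coefficient * self.dt_sub / dxx
            for n in g.FIELD_NAMES
        ])[:, None, None]
        self._decay_dt = np.array([
            self.field_params[n].decay_rate * self.dt_sub for n in g.FIELD_NAMES
        ])[:, None, None]
        self._baseline = np.array([
            self.field_params[n].baseline for n in g.FIELD_NAMES
        ])[:, None, None]
        self._vessel_values = np.array([
            self.field_params[n].vessel_value for n in g.FIELD_NAMES
        ])

        # macrophage population (constant size)
        self.macrophages: list[Macrophage] = []
        self.mac_occupancy = np.zeros(shape, dtype=bool)
        self.mac_target = int(round(self.mac_params.count_fraction * self.grid.n_sites))
        mac_mod.maintain_population(
            occ, self.mac_occupancy, self.macrophages, self.mac_target, self.rng
        )

        self.time = 0.0  # hours
        self._last_stats: StepStats | None = None

    # ------------------------------------------------------------------

    def _seed_tumour(self, n_cells: int, gly_rate: float, acid_res: float) -> None:
        """Place a roughly square tumour cluster at the grid centre."""
        if n_cells <= 0:
            return
        occ = self.grid.occupancy
        h, w = self.grid.shape
        side = int(np.ceil(np.sqrt(n_cells)))
        r0, c0 = h // 2 - side // 2, w // 2 - side // 2
        placed = 0
        for r in range(r0, min(r0 + side, h)):
            for c in range(c0, min(c0 + side, w)):
                if placed >= n_cells:
                    return
                if occ[r, c] != g.VESSEL:
                    occ[r, c] = g.TUMOUR
                    self.glyc_rate[r, c] = gly_rate
                    self.acid_res[r, c] = acid_res
                    self.age[r, c] = self.rng.uniform(0.0, self.params.division_time)
                    placed += 1

    # ------------------------------------------------------------------

    def _metabolism(self):
        """Vectorised metabolic rates (per hour) for every live cell."""
        p = self.params
        occ = self.grid.occupancy
        alive = (occ == g.NORMAL) | (occ == g.TUMOUR)
        O = self.grid.fields["oxygen"]
        G = self.grid.fields["glucose"]
        f_o = O / (O + p.k_oxygen)
        f_g = G / (G + p.k_glucose)
        rate = np.where(occ == g.TUMOUR, self.glyc_rate, 1.0)
        ox = np.where(alive, p.ox_flux_max * f_o * f_g, 0.0)
        gly = np.where(alive, p.gly_flux_base * rate * f_g, 0.0)
        atp = p.atp_per_ox * ox + p.atp_per_gly * gly
        sinks = {
            "oxygen": p.oxygen_per_ox * ox,
            "glucose": p.glucose_per_flux * (ox + gly),
        }
        sources = {"proton": p.proton_per_gly * gly}
        return atp, sources, sinks, alive

    def _relax_fields(self, sources: dict, sinks: dict) -> None:
        """Sub-step all fields at once with per-hour rates converted to per-second.

        Equivalent to calling :func:`acidmac.grid.diffuse_react` per field
        per sub-step (covered by a regression test), but vectorised over the
        stacked (n_fields, H, W) array for speed.
        """
        vessel = self.grid.vessel_mask
        stack = np.stack([self.grid.fields[n] for n in g.FIELD_NAMES])
        net = np.zeros_like(stack)
        for i, name in enumerate(g.FIELD_NAMES):
            if name in sources:
                net[i] += sources[name]
            if name in sinks:
                net[i] -= sinks[name]
        net *= self.dt_sub / 3600.0
        for _ in range(self.substeps):
            stack += self._nu * g._laplacian(stack)
            stack += net
            stack -= self._decay_dt * (stack - self._baseline)
            np.clip(stack, 0.0, None, out=stack)
            stack[:, vessel] = self._vessel_values[:, None]
        for i, name in enumerate(g.FIELD_NAMES):
            self.grid.fields[name] = stack[i]

    def _update_cells(self, atp: np.ndarray, ph: np.ndarray, dt: float) -> dict:
        """Fate transitions and divisions; returns event counts."""
        p = self.params
        occ = self.grid.occupancy
        rng = self.rng
        alive = (occ == g.NORMAL) | (occ == g.TUMOUR)

        # necrotic debris slowly dissolves, freeing the site
        if p.necrotic_lysis_prob > 0:
            necro_sites = occ == g.NECROTIC
            lysed = necro_sites & (rng.random(occ.shape) < p.necrotic_lysis_prob * dt)
            occ[lysed] = g.EMPTY

        # homeostatic turnover: normal cells apoptose at a low background
        # rate and are cleared without leaving necrotic debris
        if p.normal_turnover_prob > 0:
            turn = (occ == g.NORMAL) & (
                rng.random(occ.shape) < p.normal_turnover_prob * dt
            )
            occ[turn] = g.EMPTY

        starved = alive & (atp < p.atp_death)
        thresh = np.where(occ == g.TUMOUR, self.acid_res, p.normal_acid_threshold)
        acid_risk = alive & ~starved & (ph < thresh)
        # one uniform draw per site keeps the engine vectorised
        acid_dead = acid_risk & (rng.random(occ.shape) < p.acid_death_prob * dt)
        occ[starved | acid_dead] = g.NECROTIC

        alive = (occ == g.NORMAL) | (occ == g.TUMOUR)
        self.quiescent = alive & (atp < p.atp_quiescence)
        progressing = alive & ~self.quiescent
        self.age[progressing] += dt

        # division: only cells whose clock matured AND with a free neighbour
        free = (occ == g.EMPTY) & ~self.mac_occupancy
        has_free = np.zeros_like(free)
        has_free[:-1, :] |= free[1:, :]
        has_free[1:, :] |= free[:-1, :]
        has_free[:, :-1] |= free[:, 1:]
        has_free[:, 1:] |= free[:, :-1]
        ready = progressing & (self.age >= p.division_time) & has_free
        divisions = 0
        sites = np.argwhere(ready)
        if len(sites):
            order = rng.permutation(len(sites))
            for i in order:
                r, c = sites[i]
                if occ[r, c] not in (g.NORMAL, g.TUMOUR):
                    continue  # consumed meanwhile (cannot happen; safety)
                nbrs = mac_mod._neighbours((r, c), occ.shape)
                open_sites = [
                    s for s in nbrs
                    if occ[s] == g.EMPTY and not self.mac_occupancy[s]
                ]
                if not open_sites:
                    continue
                dst = open_sites[rng.integers(len(open_sites))]
                is_tum = occ[r, c] == g.TUMOUR
                occ[dst] = occ[r, c]
                if is_tum:
                    g_rate, a_res = tum_mod.mutate_traits(
                        self.glyc_rate[r, c], self.acid_res[r, c], p, rng
                    )
                else:
                    g_rate, a_res = self.glyc_rate[r, c], self.acid_res[r, c]
                self.glyc_rate[dst] = g_rate
                self.acid_res[dst] = a_res
                self.age[dst] = 0.0
                self.age[r, c] = 0.0
                divisions += 1
        return {
            "divisions": divisions,
            "acid_deaths": int(acid_dead.sum()),
            "atp_necroses": int(starved.sum()),
        }

    def _update_macrophages(self, ph: np.ndarray) -> int:
        occ = self.grid.occupancy
        fields = self.grid.fields
        macs = self.macrophages
        engulfed = 0
        if macs:
            self._update_behaviours_vectorised(ph)
            for mac in macs:
                summary = mac_mod.act(
                    mac, occ, self.mac_occupancy, fields, self.mac_params, self.rng
                )
                engulfed += summary["engulfed_tumour"] + summary["engulfed_necrotic"]
        mac_mod.maintain_population(
            occ, self.mac_occupancy, self.macrophages, self.mac_target, self.rng
        )
        return engulfed

    def _update_behaviours_vectorised(self, ph: np.ndarray) -> None:
        """Same maths as :func:`acidmac.macrophage.update_behaviour`, applied
        to the whole population at once (covered by an equivalence test)."""
        mp = self.mac_params
        macs = self.macrophages
        rows = np.array([m.position[0] for m in macs])
        cols = np.array([m.position[1] for m in macs])
        pro = self.grid.fields["pro_cytokine"][rows, cols]
        anti = self.grid.fields["anti_cytokine"][rows, cols]
        a = pro / (pro + mp.k_half_pro)
        c = anti / (anti + mp.k_half_anti)
        b = np.array([m.queue_count(mac_mod.QUEUE_TUMOUR) for m in macs]) / mp.capacity
        d = np.array([m.queue_count(mac_mod.QUEUE_NECROTIC) for m in macs]) / mp.capacity
        e = -0.5 * a - 0.5 * b + 0.5 * c + 0.5 * d
        if self.scenario == mac_mod.INSENSITIVE:
            p = np.full(len(macs), 7.4)
        else:
            p = ph[rows, cols]
        pro_sum = np.zeros(len(macs))
        anti_sum = np.zeros(len(macs))
        n_pro = n_anti = 0
        expr = {}
        for name, t in self.model.traits.items():
            y = t.alpha + t.beta * p + t.gamma * e + t.delta * p * e
            expr[name] = y
            norm = np.clip((y - t.ref_min) / (t.ref_max - t.ref_min), 0.0, 1.0)
            if t.polarity == mac_mod.PRO_TUMOUR:
                pro_sum += norm
                n_pro += 1
            else:
                anti_sum += norm
                n_anti += 1
        score = (pro_sum / n_pro if n_pro else 0.0) - (anti_sum / n_anti if n_anti else 0.0)
        behaviour = np.clip(score, -1.0, 1.0)
        for i, mac in enumerate(macs):
            mac.eco = mac_mod.EcologicalState(
                a=float(a[i]), b=float(b[i]), c=float(c[i]), d=float(d[i]), e=float(e[i])
            )
            mac.expression = {name: float(expr[name][i]) for name in expr}
            mac.behaviour = float(behaviour[i])

    # ------------------------------------------------------------------

    def step(self, dt: float = 1.0) -> StepStats:
        """Advance the model by one cell step (``dt`` hours)."""
        atp, sources, sinks, _ = self._metabolism()
        self._relax_fields(sources, sinks)
        ph = self.grid.ph()
        events = self._update_cells(atp, ph, dt)
        phagocytosed = self._update_macrophages(ph)
        self.time += dt

        occ = self.grid.occupancy
        n_tum = int(np.sum(occ == g.TUMOUR))
        behaviours = [m.behaviour for m in self.macrophages]
        stats = StepStats(
            time=self.time,
            n_tumour=n_tum,
            n_normal=int(np.sum(occ == g.NORMAL)),
            n_necrotic=int(np.sum(occ == g.NECROTIC)),
            takeover=tum_mod.takeover_fraction(occ),
            min_ph=float(ph.min()),
            mean_behaviour=float(np.mean(behaviours)) if behaviours else 0.0,
            divisions=events["divisions"],
            acid_deaths=events["acid_deaths"],
            atp_necroses=events["atp_necroses"],
            phagocytosed=phagocytosed,
        )
        self._last_stats = stats

        if int(self.time) % _FINITE_CHECK_INTERVAL == 0:
            for name, f in self.grid.fields.items():
                if not np.all(np.isfinite(f)):
                    raise SimulationError(
                        f"non-finite values in field {name!r} at t={self.time} h"
                    )
        return stats

    def macrophage_table(self):
        """Per-macrophage state table: time, site, behaviour, trait levels.

        This is the data behind the macrophage snapshot panel.
        """
        import pandas as pd

        rows = []
        for mac in self.macrophages:
            row = {
                "time": self.time,
                "row": mac.position[0],
                "col": mac.position[1],
                "behaviour": mac.behaviour,
                "e": mac.eco.e,
            }
            for name in self.model.traits:
                row[f"y_{name}"] = mac.expression.get(name, np.nan)
            rows.append(row)
        return pd.DataFrame(rows)

    def takeover_fraction(self) -> float:
        return tum_mod.takeover_fraction(self.grid.occupancy)

    def tumour_extinct(self) -> bool:
        return not np.any(self.grid.occupancy == g.TUMOUR)

    def run(
        self,
        takeover_threshold: float = 0.9,
        time_cap_hours: float = 87600.0,
        trajectory: Trajectory | None = None,
        record_interval: float = 0.0,
    ) -> tuple:
        """Run until takeover, extinction or the time cap.

        Returns ``(time_hours, event)`` with event 1 when the viable tumour
        exceeded the takeover threshold, else 0 (censored at the cap).  An
        extinct tumour can never take over, so the run is censored
        immediately at the cap without stepping through the remaining time.
        """
        if self.takeover_fraction() > takeover_threshold:
            return 0.0, 1
        next_record = 0.0
        while self.time < time_cap_hours:
            stats = self.step()
            if trajectory is not None and record_interval > 0 and stats.time >= next_record:
                trajectory.append(stats)
                next_record += record_interval
            if stats.takeover > takeover_threshold:
                return self.time, 1
            if stats.n_tumour == 0:
                return time_cap_hours, 0
        return time_cap_hours, 0
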
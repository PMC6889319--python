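# Methods

`acidmac` is a hybrid (agent-based + continuum) model of a glycolytic
tumour growing in vascularised tissue, built to ask one question: does
acid-driven polarisation of macrophages accelerate tumour takeover?  This
note documents the model, its assumptions, the parameters that matter, the
numerical choices, and what the synthetic components do and do not show.

## The model

### Lattice and fields

Tissue is a 2D square lattice (default 50×50; one site = one cell diameter
= 20 µm, i.e. a 1 mm patch).  A fraction of sites (default 5%) are static
blood vessels placed uniformly at random; they act as Dirichlet boundaries:
oxygen and glucose are held at their plasma values (normalised to 1),
protons are washed out to the arterial concentration (pH 7.4), cytokines to
zero.  Five diffusible fields live on the lattice — oxygen, glucose,
protons (acid), a pro-inflammatory cytokine pool and an anti-inflammatory
cytokine pool — each advanced by an explicit forward-time central-space
step with no-flux outer boundaries, operator-split as diffuse → react →
vessel reset, clipped at zero.  Acid is tracked as a proton-equivalent
concentration (mol/L), not lactate: the question under study is the effect
of pH itself, so the acid field is the primitive.  Tissue buffering is
lumped into a first-order relaxation of the proton field towards the
arterial baseline (half-life 3 h); cytokines decay with a 1 h half-life.

### Cells

Every non-vessel site initially holds a **normal cell**.  Normal cells
metabolise at baseline (one unit of oxidative glucose flux at saturation),
divide into free neighbouring sites on a 24 h clock, die below pH 6.9 (with
probability 0.3/h while below threshold) or when their ATP rate falls below
the death threshold, and additionally turn over homeostatically
(apoptosis at 0.002/h, cleared without debris).  The turnover term matters:
without it the model admits frozen states in which a suppressed tumour
cluster is permanently walled in by healthy tissue.

**Tumour cells** carry two heritable traits: a glycolytic-rate multiplier
(Warburg phenotype; initial 20× baseline, bounds [1, 40]) and an
acid-resistance threshold (the pH below which they risk death; initial 6.3,
bounds [6.0, 7.1]).  At division each trait mutates with probability 0.1 by
±0.5 (rate) or ±0.05 (pH units), so acid-mediated selection is emergent.
ATP is computed as 29·(oxidative flux) + 2·(glycolytic flux) per glucose,
with Monod limitation in both substrates (half-saturation 0.3 of the vessel
value).  Glycolytic flux exports protons (1e-8 mol/L per flux unit per
hour), which is what acidifies the microenvironment.  Cells below the ATP
death threshold become **necrotic**; necrotic material persists on the
lattice (it is the substrate of the macrophage ecological signal *d*) until
phagocytosed or until it slowly lyses (0.02/h).  Cells between the death
and quiescence thresholds are alive but their division clock is frozen.
A simulation stops with an event when viable tumour occupies >90% of
non-vessel sites.

### Macrophages

A constant population (default 4% of lattice sites) of macrophage agents
patrols the tissue.  Macrophages are interstitial: they may share a site
with a normal cell but not with tumour, necrosis, a vessel or each other.
Each hour a macrophage:

1. reads its milieu and recomputes a per-gene linear phenotype model

       y_i = alpha_i + beta_i*p + gamma_i*e + delta_i*p*e

   where `p` is the pH it responds to and the ecological variable is

       e = -0.5a - 0.5b + 0.5c + 0.5d

   with `a`/`c` the local pro-/anti-inflammatory cytokine concentrations
   normalised to [0, 1] by Michaelis half-saturation (K = 0.3), and `b`/`d`
   the fractions of its digestion capacity currently holding tumour and
   necrotic cells respectively.  The per-trait expressions are min-max
   normalised by calibration reference ranges and combined into a single
   behaviour scalar in [-1, 1]: mean(normalised pro-tumour traits) −
   mean(normalised anti-tumour traits).  The default trait pair is Ccl2
   (anti-tumour polarity) and Arg1 (pro-tumour polarity).
2. acts: with probability `p_kill*max(0, -behaviour)` engulfs one adjacent
   viable tumour cell; with probability `p_clear*max(0, +behaviour)` one
   adjacent necrotic cell (queue capacity 4; 6 h digestion per cell);
   secretes pro-inflammatory cytokine at `s_pro*max(0, -behaviour)` and
   anti-inflammatory at `s_anti*max(0, +behaviour)`; then random-walks to a
   free von-Neumann neighbour with probability 0.7 **unless engaged** — a
   macrophage with a non-empty digestion queue or an adjacent target of its
   preferred kind stays put (contact retention during phagocytosis).
   Retention is a deliberate design choice where the movement rule was
   open: without it a constant, non-chemotactic population cannot
   accumulate at the tumour boundary and has no effect in either scenario.

Macrophages neither die nor divide; deficits (none arise in-model, but the
initial population is placed this way) are filled with naive agents at
free perivascular sites.

The feedbacks close two loops: anti-tumour macrophages kill tumour,
secrete pro-inflammatory cytokine and fill their queues with tumour cells,
all of which push `e` towards −1 and reinforce the anti-tumour state;
pro-tumour macrophages clear necrotic debris (freeing space the tumour can
divide into), secrete anti-inflammatory cytokine and push `e` towards +1.
pH is the external tiebreaker between the two self-reinforcing states.

### The two scenarios

Identical in every parameter except the pH the phenotype model sees:
**sensitive** macrophages use the true local pH; **insensitive**
macrophages use 7.4 everywhere.  With the default calibration a macrophage
at pH 7.4 in an inflammatory milieu is strongly anti-tumour, while the
same milieu at pH ≤ 6.8 flips it towards the pro-tumour pole — so acid
generated by tumour glycolysis protects the tumour exactly where
protection is needed.

## Calibration

The per-trait coefficients are fit by ordinary least squares on the basis
(1, p, e, p·e) from long-format expression tables of polarisation
experiments on the 2×2 design {pH 7.4, 6.8} × {e = −1 (inflammatory
stimulus), e = +1 (anti-inflammatory stimulus)}.  With one observation per
corner the fit interpolates exactly; replicates are fit individually so
standard errors are meaningful.  Fitting is done on the fold-change scale
(FC = 2^−ΔCt for qPCR input); a log-scale option exists behind a flag.
Reference ranges for behaviour normalisation span the fitted predictions
at the design corners.

Raw per-replicate expression tables from such experiments are not
generally available, so the package ships a synthetic-expression generator:
Eq-1 predictions from configurable true coefficients plus Gaussian noise
(SD expressed as a fraction of each trait's mean prediction), truncated at
zero.  The default truths are defined by corner values chosen to reproduce
the qualitative polarisation pattern — the inflammatory marker (Ccl2:
10 → 4 at e=−1 when pH drops 7.4 → 6.8) falls under acidosis and the
alternative-activation marker (Arg1: 8 → 16 at e=+1) rises.  The magnitudes
are package choices on a fold-change scale, not measured values; what the
round-trip and recovery tests show is that the estimator recovers whatever
truth generated the data, not that these particular numbers are
biologically exact.

## Numerics

* **Time.** One cell step = 1 h; division time 24 h; the 10-year cap is
  87,600 steps.
* **Field sub-stepping and diffusivity rescaling.**  Ten field sub-steps
  per cell step.  The physical diffusivities (O2 1820, glucose 500, protons
  1080, cytokines 100 µm²/s) are far too fast for an explicit scheme at
  360 s sub-steps on a 20 µm lattice, so the engine rescales *all*
  diffusivities by one common factor placing the fastest field at the
  stability target D·dt/dx² = 0.2.  The sub-step loop then acts as a damped
  relaxation towards the quasi-steady field profile while preserving the
  relative transport speeds of the diffusibles.  Consequences: field
  *shapes* (acid niche around the tumour, hypoxic pockets between vessels,
  local cytokine halos) are qualitatively right, but absolute gradient
  length scales are lattice-scale rather than physically exact.  The
  standalone solver (`diffuse_react`) enforces the stability criterion
  strictly and conserves mass to 1e-9 relative without decay/vessels.
* **Reactions within a step.**  Metabolic source/sink rates are computed
  once per cell step from the current fields and held fixed across
  sub-steps.  Macrophage secretion is deposited as an impulse during the
  action phase.
* **Stochasticity.**  All randomness flows from one `numpy` PCG64 generator
  per replicate, seeded as base_seed + replicate index with disjoint
  per-arm blocks (arm A: base…base+n−1; arm B: base+n…base+2n−1), making
  every experiment bit-reproducible from its base seed.  Division order is
  randomised each step; conflicts are resolved sequentially.
* **Degenerate inputs.**  Zero proton concentration maps to the upper pH
  clamp (window [6.0, 7.6]); a tumour-free lattice can never reach takeover
  and is censored at the cap immediately once the tumour is extinct; a
  log-rank test with zero events raises rather than returning a number.

## The in silico trial

`run_experiment` runs n replicates per arm (desk-scale default 20;
paper-scale 100 via config), records time to >90% takeover right-censored
at 10 years, estimates Kaplan–Meier curves per arm (lifelines) and compares
arms with the one-degree-of-freedom Mantel–Haenszel log-rank test
(in-package implementation with the standard hypergeometric variance for
ties; cross-checked in the test suite against lifelines and against a
10^5-shuffle permutation null).

## Parameter calibration of the simulation defaults

The metabolic and macrophage constants are not taken from any single
source; they were chosen once, during model development, to place the
model in the regime the biology describes, and then frozen:

1. healthy tissue is viable and near-neutral (ambient pH ≥ 7.1, no
   starvation) in the absence of a tumour;
2. the seeded tumour acidifies its niche to pH ≈ 6.4–6.6, kills adjacent
   normal tissue, and takes over an unopposed 50×50 lattice in ~0.3–0.5
   simulated years;
3. pH-insensitive macrophages control and usually eradicate the tumour,
   while pH-sensitive macrophages are subverted by the acid niche and
   accelerate takeover (median ~0.15–0.2 years) by clearing necrotic
   debris at the invasion front.

Problem sizes used by the automated checks are deliberately modest so the
whole suite runs on one CPU in minutes: the scenario-separation check uses
a 32×32 lattice with 8 replicates per arm over three base seeds; the null
calibration uses 24×24 with 5 replicates per arm and a macrophage-depleted
setting (2 agents per 100 sites, both arms insensitive) because under the
headline defaults the insensitive scenario censors every replicate and a
log-rank p-value would be undefined; `scripts/acceptance.py` runs the full
desk-scale profile (50×50, 20 per arm).

## What the synthetic data does and does not show

The synthetic-expression generator and the simulation defaults emulate the
*structure* of the biological claim — a pH-dependent, milieu-dependent
continuous macrophage phenotype embedded in an evolving metabolic
landscape — not any specific measured magnitudes.  Passing tests therefore
demonstrate internal consistency (estimators recover generating truths;
the statistical pipeline is calibrated; the mechanism produces the claimed
ordering robustly across seeds), but they cannot validate the model
against real tumours.  Known limitations: 2D lattice; static vasculature;
no bicarbonate buffering chemistry (first-order relaxation instead); no T
cells or adaptive immunity (deliberate — the modelled cancer is
immunologically cold); no macrophage chemotaxis, death or proliferation;
opsonisation absorbed into the kill probability; a two-trait behaviour
readout where the underlying biology is many-dimensional.
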
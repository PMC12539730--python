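# Model and methods

## The excitable core

The membrane of an amoeboid cell is modelled as a periodic 1-D lattice of
`n_points = 126` sites with spacing `dx = 0.25 μm` (circumference 31.5 μm,
a typical *Dictyostelium* perimeter).  Three species live on it:

* **Ras** — the front activator.  Produced at rate
  `a3 / (1 + a4² [PIP2]²) + a5`: PIP2 gates Ras production with an
  effectively switch-like (squared-Hill) dependence, plus a small leak
  `a5`.  Degraded at rate `(a1 + a2 [PKB]) [Ras]`.
* **PIP2** — the back inhibitor.  Produced at a constant rate `b3` and
  consumed at `(b1 + b2 [Ras]) [PIP2]`; high Ras depletes PIP2, which in
  turn releases Ras production — the mutual-inhibition loop that provides
  the positive feedback required for excitability.
* **PKB** — the slow refractory species, produced by Ras (`c2 [Ras]`) and
  decaying at `c1` (time constant ≈ 54 s).  PKB terminates each excursion
  and enforces a refractory period.

The resting state is the unique stable equilibrium (Ras ≈ 0.0026 μM,
PIP2 ≈ 0.354 μM, PKB ≈ 0.030 μM with default constants); firings are
noise-triggered, all-or-none excursions away from it.

Two of the published rate constants carry units that identify their roles
unambiguously but conflict with the symbols they were printed against:
0.4920 μM s⁻¹ can only be the zero-order PIP2 production and
533.5 μM⁻¹ s⁻¹ the Ras-stimulated hydrolysis coefficient.  We assign them
accordingly (`b3 = 0.4920`, `b2 = 533.5`); with the roles reversed the
network has no excitable regime at all (basal PIP2 ≈ 10⁵ μM shuts Ras
production off permanently).

### Diffusion

`D_ras = D_pkb = 0.0075 μm²/s` and `D_pip2 = 0.0225 μm²/s`.  The lateral
inhibitor diffusing a few-fold faster than the activator is the classical
local-activation / lateral-inhibition configuration, and it is the setting
in which the simulated membrane reproduces the expected phenomenology:
occasional firings that propagate as V-shaped wave pairs and extinguish,
Ras/PKB firing durations of roughly 40 s / 110 s, and an autocorrelation
that is gone within a minute.  The source parameter table instead lists a
single large coefficient (0.225 μm²/s, retained as `StenParams.d_fast`)
against an ambiguous species label while the accompanying text calls the
inhibitor only "slightly faster"; we found that assigning 0.225 to any one
species destroys this phenomenology (assigned to PKB it produces permanent
turbulent stripes with PKB elevated for the entire run; assigned to PIP2
or Ras the system falls silent at the stated noise level), so the package
default follows the text.  This choice was calibrated once against the
baseline firing statistics and then frozen.

### Noise and integration

Each core species receives Langevin noise of standard deviation
`α √(gain + loss)` per unit time (`α = 0.091`), i.e. fluctuations scale
with the total local reaction flux.  Integration is explicit
Euler–Maruyama, `dt = 0.01 s` (well inside the diffusive stability bound
`dx²/2D ≈ 1.4 s`), with concentrations clipped at zero after each step.
Clipping slightly biases small concentrations upward relative to a
reflecting scheme; at the default parameters the affected species (PIP2 at
an active front) is pinned near zero either way.  States are recorded
every 1 s.  Each simulation draws one independent noise stream per species
(keyed by `(seed, species)`), so enabling a feedback loop never perturbs
the noise seen by the core species — with all loop strengths at zero the
trajectory is bit-for-bit identical to the bare network.  The inner loop
is compiled with numba; a NumPy reference `step` is cross-checked against
it in the test-suite.

## Feedback loops

* **Branched actin** `P_act`: driven by PKB (`p2`), first-order decay
  (`p1`), slow diffusion; multiplies Ras production by
  `1 + a_act · P_act`.  With `p1 = p2` its equilibrium tracks the local
  PKB level; its 80 s lifetime is the "memory" that lets previous firings
  promote new ones in place.
* **Myosin** `P_myo`: driven by PIP2 (a rear signal), multiplies Ras
  *degradation* by `1 + a_myo · P_myo` — local inhibition rooted at the
  rear (model 1).
* **Tension** `P_ten`: a single scalar driven by the spatial mean of PKB —
  global inhibition (model 2).  Default coupling multiplies Ras
  degradation (`1 + a_ten·P_ten`); a variant divides Ras production by the
  same factor (the GEF-reduction scheme).  On spatially uniform states the
  two architectures coincide with a local loop driven by the same input.
* **PIP5K** (model 3): total-conserving two-state exchange.  Ras releases
  the membrane-bound form at rate `p7 [Ras]²/(1 + p9²[Ras]²)`; the unbound
  form rebinds at `p8` and diffuses twice as fast.  The active pool
  (bound, unbound, or their sum — `pip5k_mode`) multiplies PIP2 production
  by `1 + a_pip5k · active`.  The exchange is advanced with its exact
  per-site solution (linear once Ras is frozen over a step), so total
  PIP5K is conserved to round-off over full runs.  Initial condition: all
  bound, uniform, total 1 per site.

P_act and P_myo carry the same reaction-flux Langevin noise as the core
species; P_ten and PIP5K are deterministic.  Feedback fields start at
their equilibria given the basal core state.

## Firing statistics and autocorrelation

Firing detection thresholds are expressed as a fraction of the mean
excited-trace peak above basal: 3 % for Ras (tall, narrow spikes ≈ 190×
basal) and 20 % for PKB (which rides a slow decay tail); events shorter
than 10 s are dropped and gaps shorter than 30 s merged.  These
conventions were calibrated once against the published baseline firing
durations and then frozen; they are deliberately per-species — no single
fraction reproduces both species' published durations.

Temporal autocorrelation is computed per spatial site on mean-subtracted
traces with the biased (1/N) estimator, then averaged over sites and
replicates; zero-variance traces are flagged and assigned zero at positive
lags.

Under strong actin feedback our model ignites once and the whole perimeter
then stays active; such single-step traces have slightly *negative*
long-lag autocorrelation, whereas a long-lag plateau of ≈ 0.35 (as
reported for that regime) requires sites that keep switching between
persistent high and low states.  The package computes and reports the
statistic either way; this regime difference is a known limitation of our
parameter reading (see Limitations).

## Patch analysis and polarization

The PKB kymograph is binarized (default threshold: midpoint between the
basal level and the mean excited peak), and connected components are
extracted with 8-connectivity, merging components that touch both spatial
edges at overlapping times (the membrane is a ring; wrapped components are
measured in unwrapped coordinates).  Patches smaller than 50 pixels are
discarded.  Each patch carries its area, time extent, angular extent, and
the orientation of its second-moment ellipse relative to the time axis
(pixel units, 1 s × 1 site).

Front counting uses patches with orientation < 30°; the dominant front
count is the statistical mode over recorded times (ties broken toward the
smaller count).  A simulation is classified **polarized** when (i) the
dominant count is one, (ii) more than 10 % of the simulation is spent in
the single-front state, and (iii) the largest patch's orientation does not
exceed 60°.  An alternative classification (dominant count one and mean
patch width < 60°) is selectable; on our simulations it is substantially
stricter, because persistent active states tend to span the ring rather
than form narrow fronts.

## Mean-field analysis

With diffusion and noise removed, every auxiliary species is an explicit
function of Ras at equilibrium, so all equilibria are roots of a scalar
function of Ras; roots are located on a dense logarithmic grid and
polished by Brent's method (merge tolerance 10⁻⁶ μM), and stability comes
from the analytic Jacobian (cross-checked against finite differences; the
PIP5K conservation mode's structurally zero eigenvalue is excluded).

The **activation threshold** is the smallest instantaneous Ras kick whose
trajectory crosses a mid-excursion criterion, found by bisection to
10⁻⁴ μM.  The criterion is halfway between the basal state and an excited
peak probed with a fixed 1 μM kick, evaluated per parameter point
(default) or once on a reference system.  The threshold landscape at
large PIP5K levels is sensitive to this construction — with the per-point
criterion the threshold has an interior maximum near level 3 on [1, 8],
with the reference criterion it increases monotonically; the per-point
variant is the default because it reproduces the biphasic shape observed
for this system.  A 0.2 μM probe resolves the excitability knee of the
bare network and is used in the all-or-none test.

The **PIP5K level** axis of the bifurcation scans is a scalar multiplying
the PIP2 production rate, normalised so level 1 is the reference system.
Scans at actin strength 1 and myosin strength 0.3 locate: the level where
the low-Ras branch's leading eigenvalue crosses zero (bisection; ≈ 0.47 —
the branch is lost in a fold), and the largest level at which the system,
continued from the low state, settles onto an attractor with Ras above 10×
the reference basal value (≈ 0.47; below the fold the only attractor is
the high-activity branch, which exists up to level ≈ 0.75 but is not
reached from the low state while that state persists).

## Motility

PKB activity above a threshold (default: midpoint between basal and the
99th-percentile excited level) generates outward normal stresses
proportional to PKB; their vector sum is rescaled per run so its maximum
equals the top of the observed protrusive-stress range (5 nN/μm) and
drives the viscoelastic equation per axis.  Because the system is linear
with piecewise-constant input, each recording interval is advanced with
the exact solution (the σ̇ term contributes an impulsive velocity jump
`(1/γ_c + 1/γ_a) Δσ`), which is unconditionally stable.  Displacements are
normalised post hoc so the maximum centroid speed is 10 μm/min — per run
by default, or with a shared scale across a sweep so conditions remain
comparable.  The cell is a rigid circle; no shape deformation.

## Synthetic kymographs

`stenpol.synth` renders kymographs with known ground truth: constant
background, i.i.d. Gaussian pixel noise, and rectangular or elliptical
patches of specified centre, duration, angular width, orientation and
amplitude (periodic wrap in angle; angular offsets are converted to
time-pixel units before rotation so orientations match the pixel metric
used by the patch pipeline).  This exercises binarization, labelling,
moments and the classification rules independently of the simulator, and
is how the stated recovery tolerances (width ± 1 site, duration ± 1
recording interval, orientation ± 3°) are verified.  What it does not
emulate: spatially correlated noise, wave-shaped (V) events, gradual
amplitude ramps — recovery on real simulator output is additionally
exercised end-to-end in the polarization tests.

## Problem sizes

The default study conditions are 1200 s simulations on 126 sites.  The
test-suite and the acceptance script use ensembles of 4 replicates for
baseline statistics, 20 replicates per grid cell for polarization counts,
and a 3 × 3 grid × 5 replicates for the qualitative sweep monotonicities.

## Known limitations

* The published parameter table is internally inconsistent (units vs
  symbols for the PIP2 constants; diffusion-coefficient labels vs the
  text); the package resolves both in favour of the reading that yields an
  excitable medium, but the original implementation's exact regime cannot
  be recovered from the printed values.  Consequences observed here: the
  mean-field stability loss sits at PIP5K level ≈ 0.47 rather than ≈ 0.6,
  and the strong-feedback regime activates the whole membrane rather than
  maintaining narrow persistent fronts (hence no positive long-lag
  autocorrelation plateau, and polarized states whose patch width spans
  the ring).
* Explicit Euler–Maruyama with clipping is first-order and biased for
  near-zero concentrations; the recorded dynamics are discretisation-
  sensitive at the ~10 % level (halving `dt` shifts the mean baseline Ras
  firing duration from ≈ 39 s to ≈ 36 s).  `dt = 0.01 s` is part of the
  frozen study conditions.
* The motility model's stress scaling (per-run max-normalisation into the
  protrusive-stress range) makes absolute speeds comparable only within a
  normalisation group.
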
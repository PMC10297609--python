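# Methods

This note records the model as implemented, the defaults and why they hold,
the numerical machinery, and the design choices made where the problem was
genuinely open. Units are micrometres, milliseconds and millimolar
throughout; configuration values quoted in nanometres are converted at the
dataclass boundary.

## Environment generation

The neuropil is a Boolean model: spheroid centres are sampled uniformly in
the arena box **inflated by the maximum radius** (so coverage is spatially
stationary right up to the walls; sampling centres only inside the arena
would artificially thin coverage near the faces), radii uniform on
[`r_min`, `r_max`] = [50, 300] nm. A candidate is rejected if its centre
lies within `radius + 145 nm` of the release site — 135 nm is the farthest
reach of the cleft slab and the two hemispheric obstacles from the origin,
plus the 10 nm minimum gap. This conservative ball-shaped exclusion
guarantees no spheroid surface approaches the cleft region within the gap.

Spheres are added until the running Monte Carlo estimate of the
extracellular fraction (2×10⁵ fixed test points per realisation) first
reaches the target α; the overshoot from the final sphere is ≲ 5×10⁻⁴ in
fraction. Roles are then assigned by independent Bernoulli draws with
initial probability `VF_astro / (1 − α)`, re-measured on the same test
points under the ownership rule below, and the probability rescaled and the
roles redrawn until the measured astroglial fraction is within the 0.01
tolerance (typically 1–3 iterations). Unreachable targets (too few spheres
allowed, inconsistent fractions) raise with a diagnostic rather than
looping.

**Ownership rule.** A point inside several spheres belongs to the sphere
whose surface is farthest inside (maximum `radius − distance`), ties to the
lowest sphere index. The same predicate backs test-point classification,
astroglial-fraction measurement and shell-volume estimation, so all volume
accounting is mutually consistent.

**Cleft model.** The cleft is a 120 nm wide, 20 nm high cylindrical void at
the origin; release happens uniformly inside it. Two hemispheric reflective
obstacles of 250 nm diameter sit on the cleft faces (flat discs towards the
cleft, domes away) and represent the pre- and postsynaptic elements. The
apposition diameter is taken as 250 nm; the quoted "~250 µm" in the source
figure caption is treated as a typographical slip, since a quarter-millimetre
apposition is anatomically impossible and inconsistent with the rest of the
geometry.

## Brownian dynamics and collisions

Free particles take isotropic Gaussian steps with per-axis variance
`2 D dt`; D defaults to 0.5 µm²/ms (in situ extracellular diffusivity).
The step is resolved against all solids by **mirror reflection**: the
segment–sphere entry point is found from the quadratic, the remaining
segment is reflected about the tangent plane, and the procedure iterates (up
to 8 times) until the endpoint is valid. Arena walls reflect by folding
(an "open" mode flags leavers as escaped instead). Hemispheres reflect off
their flat disc when the segment crosses it, otherwise off their spherical
surface. In narrow wedges between strongly overlapping spheres the
reflection sequence occasionally fails to settle within the cap
(≈ 0.03% of particle-steps at baseline); such steps are rejected — the
particle stays at its step-start position, which is always valid. Containment
tests carry a 10⁻⁶ µm tolerance so a point placed numerically on a surface by
one reflection does not re-trigger it.

**Time step.** The source model never states dt. The default
dt = 2×10⁻⁵ ms gives an rms 3-D step of 7.7 nm, comparable to the 5 nm
transporter proximity shell; a resolution guard rejects configurations whose
rms step exceeds twice the proximity cutoff, because endpoint-sampled
contact would otherwise become strongly step-size dependent. (Binding
*kinetics* are dt-exact by construction — see below — only contact
*detection* needs the guard.)

**Performance machinery** (no physics content): spheres live in a uniform
spatial hash whose per-cell lists include every sphere within a 90 nm margin
of the cell, so single-cell queries have no false negatives. Each particle
carries a packed neighbour list (spheres with surface within 60 nm of an
anchor point, rebuilt when the particle moves 30 nm from the anchor) and a
certified safe-distance budget: while the cumulative L1 step length stays
below the measured distance-to-nearest-surface minus the proximity cutoff,
collision and contact tests are provably unnecessary and are skipped. The L1
bound makes the fast path exact, not heuristic; near-path (collision-checked)
moves also consume budget through the √3·L1 bound on the reflected
displacement.

**Randomness.** Brownian increments are pre-generated per (condition, run)
as a float32 `(steps, particles, 3)` stream and indexed by (step, particle),
so the paired unbinding-on/off arms consume *identical* diffusion noise even
after their particle states diverge. Binding and fate draws use a separately
seeded per-run generator; the unbinding delay is drawn even when the fate is
translocation so those streams stay aligned across arms until the first
actual release. Every seed derives from the master seed via
`SeedSequence(master, spawn_key=(condition, run, role))`, making any single
run reproducible in isolation.

## Transporter binding and unbinding

While a free particle's endpoint lies within 5 nm of an astroglial surface,
binding is sampled each step with the incremental hazard
`h = 1 − exp(−dt/Ψ)` conditioned on not yet being bound, which makes the
cumulative binding probability after continuous contact time `t` equal
`1 − exp(−t/Ψ)` *exactly, for any dt*. The contact clock resets on departure
beyond the cutoff. Ψ (default 1 ms) lumps transporter affinity, surface
density and geometric proximity; it is the model's one free parameter and is
calibrated by grid search against a reference bound-glutamate spatial
profile (both profiles normalised to unit peak — a fluorescence reference
and a concentration profile share only shape).

Each binding event draws a fate: unbind with probability 0.35, else
translocate. Unbinding delays follow the cumulative-Gaussian schedule with
median 4 ms and σ = 2 ms; the *analytic* schedule is the untruncated
Gaussian CDF (exactly 0.5 at 4 ms), while *sampled* delays are truncated at
zero by resampling (mass ≈ 0.023), which shifts the sampled median to
≈ 4.06 ms — an accepted approximation, kept because a negative delay is
meaningless. Released particles resume diffusing from their binding
position and may re-bind; translocation-fated particles stay
transporter-bound for the remainder of the run (real translocation takes
tens of milliseconds, beyond the ≤ 10 ms window) and are counted in the
bound-concentration readout.

**A consequence worth stating plainly.** With this kinetically exact hazard,
the fraction of time a diffusing particle spends within the 5 nm shell of
astroglial surfaces at baseline geometry is ≈ 1%, so with Ψ = 1 ms only
~10% of released particles bind within 9 ms, and unbinding returns only a
few percent of the release to the extracellular pool. Model variants in the
literature that compare the *cumulative* P against a fresh uniform draw
every step behave instead like absorption on contact (binding after
~√(2 Ψ dt) of contact) and produce much stronger uptake and a much larger
unbinding contrast. This implementation deliberately keeps the exact
first-order law — it is the stated model — and reports the contrast it
actually produces; see "Known limitations".

## Profiles and concentrations

Snapshots are binned into 20 nm concentric shells about the release site;
the grid extends to the arena corner radius (L√3/2) so every in-arena
particle falls in exactly one shell and counts are conserved exactly.
Per-shell extracellular volumes are Monte Carlo estimates from points drawn
uniformly *inside each shell* (default 1000 per shell; uniform-in-volume via
inverse-CDF on r³), classified by the environment predicate; sampling per
shell rather than arena-wide keeps thin near-cleft shells well resolved.
Concentration is `scale × count / (N_A × V_ec)` in mM, with scale = 3
mapping 1000 simulated particles onto a ~3000-molecule vesicle; shells with
particles but zero measured extracellular volume are flagged NaN, never
silently dropped. Averaging across runs is pointwise mean ± SEM (ddof = 1).

Recorded time points default to 0.1, 0.5, 1, 2, 4, 6, 8 and 9 ms; runs last
9 ms.

## NMDA receptor kinetics

The 5-state scheme U ⇌ C1 ⇌ C2 with glutamate-dependent forward rates, plus
C2 ⇌ D (desensitised) and C2 ⇌ O (open), is integrated as a linear
time-varying ODE (LSODA, rtol = atol = 10⁻⁸) from U = 1, driven by the
averaged free-glutamate transient at a chosen distance, linearly
interpolated and extended past the simulated window with zero (or held,
configurable) out to 300 ms so slow receptor kinetics complete. Probability
conservation along trajectories is ≤ 10⁻⁷ in tests; the constant-drive
stationary state is cross-checked against a null-space computation of the
generator matrix.

Rate constants ship in `src/gluspill/data/nmdar_5state.yaml` and default to
the published nmda5 five-state set (Destexhe, Mainen & Sejnowski 1994/1998:
kon 5×10⁶ M⁻¹s⁻¹, koff 12.9 s⁻¹, desensitisation 8.4 s⁻¹, resensitisation
6.8 s⁻¹, opening 46.5 s⁻¹, closing 73.8 s⁻¹). The file is data, not code:
any other published 5-state parameterisation can be dropped in.

**Metrics.** "Activation" is reported as open probability; "double
occupancy" defaults to C2 + O. The desensitised state, though doubly
liganded, cannot open on depolarisation, and the functional meaning of a
"tagged" receptor is one primed to open — so D is excluded by default and
includable by flag. Tag duration is the maximal contiguous interval with
double occupancy ≥ 5% of its own peak. With the nmda5 rates the
doubly-bound pool has a ~310 ms slow eigenmode (desensitised-state
recycling), so tag durations measured in a 300 ms window sit at the window
edge regardless of drive amplitude — a property of this rate set, reported
as such.

## What the synthetic data does and does not emulate

All inputs are parametric; the generator *is* the study system. It emulates:
stationary isotropic sphere-packing neuropil at controlled α and VF_astro,
instantaneous single-vesicle release, non-saturating transporter supply, and
linear scaling of concentration with molecule count. It does not emulate:
real cell morphologies (dendrites, spines, sheet-like astroglial leaflets),
spatial correlation between astroglial coverage and synapse location,
transporter surface densities or saturation, ion-coupled transporter cycles,
Mg²⁺ block or voltage dependence of NMDARs, or optical reporter physics
(point-spread, dwell time). Passing tests therefore demonstrate internal
consistency of the stated stochastic model at its stated parameters — not
that real perisynaptic glutamate behaves quantitatively this way.

## Problem sizes in the shipped tests and scripts

The test suite runs the paired baseline at 5 environment realisations ×
1000 particles × 9 ms (the "desk" preset; the "paper" preset uses 10 runs),
re-validates volume fractions over 20 fresh environments at 2.5×10⁵ test
points each, and recovers Ψ on a reduced 3 µm arena with 400 particles and
2 runs per grid value. The acceptance script uses 10⁵ particles for the MSD
regression and 10⁶ test points per environment. These sizes were chosen so
a full check completes on a single workstation core in well under half an
hour while keeping every statistical tolerance comfortably resolved.

## Known limitations

- The exact first-order binding hazard with endpoint-sampled 5 nm contact
  yields weak total uptake at Ψ = 1 ms (see above). The across-arm
  unbinding contrast on distal NMDAR activation is correspondingly small
  (~1%, versus the ~two-fold contrast reported for implementations with
  near-absorbing contact kinetics). The package reports what the stated
  model produces.
- The nmda5 rate set's slow desensitised-state recycling makes 5%-of-peak
  tag durations exceed the 300 ms analysis window; faster-unbinding
  published sets (e.g. Lester–Jahr 1992) give ~40 ms instead. The scheme
  file is swappable precisely because this choice dominates the tag metric.
- Reflection in deep sphere-overlap wedges rejects ~0.03% of steps, which
  infinitesimally stiffens diffusion in the tightest voids.
- The cleft exclusion zone is a conservative ball, so a thin shell around
  the cleft is slightly emptier than strict necessity.
- Shell concentrations beyond r ≈ 1.5 µm feel the reflective arena walls at
  late times (the arena becomes well mixed by ~10 ms); the open-wall mode
  trades this for particle loss.
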
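# gluspill

Monte Carlo simulator of **glutamate spillover in a probabilistic synaptic
neuropil**: release of a vesicle's worth of glutamate into a synaptic cleft,
Brownian diffusion through a randomly generated scatter of neuronal and
astroglial obstacles, stochastic binding to astroglial glutamate transporters
(GLT-1-like), delayed transporter *unbinding* that re-releases a share of the
bound glutamate, and activation of extrasynaptic NMDA receptors up to a
micron from the release site.

The package is for computational neuroscientists who want to ask how far a
synaptic glutamate discharge can act, and how astroglial transporter binding
and unbinding shape that reach, without committing to a single "average"
tissue geometry: every run draws a fresh environment, so rare transporter-free
escape routes survive in the across-run average.

## Model

**Environment.** A cubic arena (edge `L` = 4 µm) is filled with overlapping
spheroids, radii uniform on [50, 300] nm, until the Monte Carlo estimate of
the extracellular volume fraction reaches the target α (hippocampal baseline
α ≈ 0.2). Each spheroid is astroglial with a probability tuned so the
astroglial tissue fraction matches VF_astro (≈ 0.1 hippocampus, ≈ 0.3
cerebellum). A 120 × 20 nm cylindrical cleft sits at the centre between two
hemispheric obstacles (250 nm apposition); fractions are re-validated per
realisation with uniform test points.

**Diffusion.** N = 1000 particles are released uniformly in the cleft and
take isotropic Gaussian steps with per-axis variance 2 D dt
(D = 0.5 µm²/ms, dt = 2×10⁻⁵ ms), reflecting elastically (mirror rule) off
every surface. Tortuosity is emergent, not imposed.

**Transporters.** While a particle dwells within 5 nm of an astroglial
surface its cumulative binding probability follows the first-order law
P = 1 − exp(−t/Ψ) (per-step hazard 1 − exp(−dt/Ψ), so the law holds exactly
for any dt); the contact clock resets when it leaves the shell. Each binding
event unbinds with probability P_unbind = 0.35 after a delay drawn from a
cumulative-Gaussian schedule (median 4 ms, σ = 2 ms), otherwise the molecule
stays transporter-bound (translocation takes far longer than the ≤ 10 ms
simulated window). Ψ is a free parameter calibrated by grid search (0.1–10
ms) of the simulated bound-glutamate spatial profile at 4 ms against a
reference profile.

**Readouts.** Free and bound molecules are counted in 20 nm concentric
shells; counts over Monte Carlo extracellular shell volumes give absolute
concentrations (×3 scaling emulates a ~3000-molecule vesicle), averaged over
≥ 5–10 environment realisations (mean ± SEM). The averaged free-glutamate
transient at any distance drives a 5-state NMDA receptor scheme
(U ⇌ C1 ⇌ C2 ⇌ O, C2 ⇌ D; rates from the published nmda5 parameter set,
swappable via a YAML file) integrated at 10⁻⁸ tolerance, yielding open
probability, double occupancy (C2 + O) and the "tag" duration a receptor
stays primed for opening.

## Worked example

```bash
python examples/generate_environment.py
```

prints (seed 42):

```
spheroids placed:        4688
astroglial spheroids:    582
alpha   target 0.20  ->  measured 0.2017 +/- 0.0006
VF_astro target 0.10 ->  measured 0.1015 +/- 0.0004
spheroid table written to environment_seed42.csv
```

i.e. one fresh 4 µm neuropil realisation whose extracellular and astroglial
fractions, re-measured with independent test points, land within ~0.01 of
the hippocampal targets. The other scripts in `examples/` follow the same
pattern: `free_diffusion_check.py` (Einstein-relation recovery of D),
`transporter_kinetics.py` (binding law, fate split, release schedule),
`paired_unbinding.py` (variance-reduced unbinding-on/off contrast),
`nmdar_activation.py` (receptor metrics from a transient), and `fit_psi.py`
(Ψ grid-search calibration against a synthetic reference profile).

A thin CLI wraps the same library calls:

```bash
gluspill simulate --outdir out --preset desk --seed 1
gluspill reproduce fig2 --outdir out_fig2 --preset desk
```

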
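# bilayerlens

Quantitative analysis of how steroids (cholesterol, progesterone) reshape
lipid membranes, combining the three experimental readouts used in membrane
biophysics — FRAP diffusion, domain morphometry, Laurdan spectroscopy — with
structural analysis of atomistic bilayer trajectories, and a synthetic-data
generator that makes every estimator testable against known ground truth.

## Who it is for

Membrane biophysicists comparing sterol effects on supported lipid bilayers
(SLBs) and simulated bilayers: how fast do lipids diffuse, how do
phase-separated domains look, how hydrated is the probe environment, where
does the steroid sit and how does it tilt, how ordered are the acyl chains,
how much lateral area does each lipid occupy.

## The quantities it computes

**FRAP (`bilayerlens.frap`).** Fluorescence recovery into a uniformly
bleached disk of radius *w* by pure lateral diffusion follows the Soumpasis
solution, used here in its modified form

    f(t) = a · e^(−2τ_D/t) [ I₀(2τ_D/t) + I₁(2τ_D/t) ] + b,   τ_D = w² / (4D)

with I₀, I₁ modified Bessel functions, *a* the recovery amplitude and *b*
the post-bleach baseline. The mobile fraction is R_mobile = a / (1 − b).
Traces are double-normalised against a reference region before fitting.

**Domain morphometry (`bilayerlens.domains`).** 3×3 mean smoothing,
threshold binarisation (Otsu or fixed), connected-component labelling,
per-domain circularity 4π·area/perimeter² (Crofton perimeter), a minimum
equivalent-diameter filter (default 3 µm), and the Shannon entropy
SH = −Σ P(x) log₂ P(x) over domain-size bins as a scalar heterogeneity
measure.

**Laurdan spectra (`bilayerlens.spectra`).** The spectral centre of mass
Σ λ·I(λ) / Σ I(λ) (trapezoid-weighted, default window 400–550 nm) tracks
membrane hydration/fluidity; shifts are reported against the 0 mol%
reference with blue shift negative.

**Bilayer trajectories (`bilayerlens.bilayer`).** On named-atom coordinate
trajectories (multi-frame PDB):

- partial density profiles along the membrane normal and bilayer thickness
  as the peak-to-peak distance of the leaflet phosphorus density maxima;
- steroid ring-centre depth (equal-weight centre of the C3/C8/C10/C13/C16
  ring scaffold) and tilt Θ of the C3→C16 axis against the outward leaflet
  normal, with joint tilt–depth histograms;
- acyl-chain order parameters S_CH = ⟨(3 cos²θ − 1)/2⟩ per carbon with
  5-block standard errors and ΔS_CH difference profiles;
- area per lipid via per-leaflet periodic Voronoi tessellation of projected
  reference atoms (phosphorus for phospholipids, the C3-bound oxygen for
  steroids);
- lateral MSD with D = slope/4 fitted on a configurable lag window
  (default 30–70 ns).

**Synthetic data (`bilayerlens.synthetic`).** Generators for every input
class with the generating parameters recorded: Soumpasis traces, two-phase
domain images, Gaussian emission spectra, geometric bilayers (90
phospholipids + 30 steroids per leaflet by default, prescribed thickness,
APL, ring depth, tilt mode and per-carbon S_CH targets), and periodic 2-D
Brownian walkers with known D.

## Worked example

```python
import numpy as np
from bilayerlens import synthetic, frap, bilayer

# fit a noisy synthetic FRAP trace generated at D = 1.74 um^2/s, w = 5 um
trace = synthetic.make_frap_trace(
    synthetic.SyntheticFrapSpec(diffusion_um2_s=1.74, noise_sd=0.02, seed=0))
fit = frap.fit_recovery(trace)
print(f"FRAP fit: D = {fit.diffusion_um2_s:.3f} um^2/s, "
      f"tau_D = {fit.tau_d_s:.2f} s, R_mobile = {fit.mobile_fraction:.3f}")

# structural analysis of a synthetic bilayer (defaults: thickness 38.3 A,
# APL 64 A^2, steroid ring depth 8 A)
spec = synthetic.SyntheticBilayerSpec(n_frames=50, seed=0)
traj = bilayer.assign_leaflets_and_center(synthetic.make_bilayer_trajectory(spec))
prof = bilayer.partial_density_profile(traj, resname="DOPC", name="P")
print(f"thickness = {bilayer.membrane_thickness(prof):.2f} A")
apl = bilayer.voronoi_apl(traj)
print(f"APL (all) = {apl.per_class['all']['mean']:.1f} +/- {apl.per_class['all']['sd']:.1f} A^2")
rprof = bilayer.ring_center_profile(traj, "CHL")
zmax = float(np.max(np.abs(rprof.z_centers_A)))
print(f"steroid ring-centre peak at {bilayer.profile_peak(rprof, (0, zmax)):.2f} A")
```

prints

```
FRAP fit: D = 1.798 um^2/s, tau_D = 3.48 s, R_mobile = 0.997
thickness = 38.33 A
APL (all) = 64.0 +/- 4.7 A^2
steroid ring-centre peak at 8.05 A
```

The fitted D recovers the generating 1.74 µm²/s within the noise of a
single trace; thickness, area per lipid and ring depth land on the
generator's targets (38.3 Å, 64 Å², 8 Å).

There is also a pipeline CLI: write a YAML task list and run
`bilayerlens run --config run.yaml`; subcommands (`bilayerlens frap fit`,
`bilayerlens domains analyze`, `bilayerlens spectra com`,
`bilayerlens bilayer analyze`) expose the individual analyses. Every run
writes a manifest with a config hash and the produced files; synthetic
tasks are byte-reproducible given the same config and seed.

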
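# Methods

This note documents the models, estimators, numerical choices and known
limitations of bilayerlens, and what the synthetic-data generators do and
do not emulate.

## FRAP recovery fitting

The modified Soumpasis model describes recovery into a uniformly bleached
disk by pure 2-D diffusion:

    f(t) = a · e^(−2τ_D/t) [I₀(2τ_D/t) + I₁(2τ_D/t)] + b,  τ_D = w²/(4D).

Assumptions: a sharp circular bleach profile of radius *w*, a single
diffusing species, no flow, no binding. The default *w* is 5 µm — the
radius of a 10 µm-diameter bleach spot; since D is quadratic in *w*, the
radius-vs-diameter convention is stated explicitly wherever *w* enters.

Numerics. The Bessel product is evaluated with exponentially scaled
functions `i0e`/`i1e` so `exp(−x)(I₀+I₁)` stays finite as t→0 (x = 2τ_D/t
diverges); at t = 0 the limiting value *b* is returned. Fitting uses
unweighted least squares (`scipy.optimize.curve_fit`) with scale-free
initial guesses — b from the minimum intensity, a from the range, τ_D from
the half-recovery time — and bounds a, b ∈ [0, 1.5], τ_D ∈ [10⁻³, 10⁴] s.
A trace with no recovery amplitude is reported as non-converged with D
undefined rather than forced through the optimiser. Mobile fractions
outside [0, 1] are reported raw alongside a clipped value and a flag,
never silently truncated.

Normalisation assumes the reference series (whole image minus the bleach
spot) shares the acquisition photobleaching of the bleach ROI, so the
ratio divides drift out; the pre-bleach ratio sets the scale.

## Domain morphometry

Processing order: 3×3 mean smoothing (edge pixels average the in-bounds
neighbourhood, avoiding zero-padding dimming), binarisation (Otsu default,
fixed threshold optional; foreground = dark, dye-excluded phase, with an
inversion flag), 8-connected labelling (4-connectivity available),
measurement, then a minimum equivalent-diameter filter (default 3 µm,
safely above the diffraction limit).

Perimeter and circularity. Perimeters use the Crofton multi-direction
estimator: naive pixel-edge counting overestimates a disk's perimeter by
~4/π, which would push disk circularity to ≈0.785. With Crofton, a disk of
radius 20 px measures ≥0.95 and an axis-aligned square reads slightly
above its analytic π/4 (corners are smoothed); the estimator choice is
recorded in the result provenance because circularity values depend on it.
Circularity is capped at 1.0. Border-touching domains are excluded from
circularity statistics (truncated outlines bias the perimeter) but kept in
area totals and entropy.

Entropy binning. The size-distribution entropy depends on the bin scheme
and log base, neither of which has a universal convention. Default: every
distinct integer pixel area is its own bin ("fine"), log base 2; a
fixed-width linear scheme in µm² is available. Both are recorded in the
distribution object, and entropies should only be compared across images
analysed with identical settings and pixel sizes.

## Spectral centre of mass

COM = Σ w·λ·I / Σ w·I with composite-trapezoid weights w, correct on
non-uniform wavelength grids. Default window 400–550 nm (the Laurdan
emission band transmitted by a 380 nm long-pass detection path);
configurable, and COM values are only comparable within one window choice,
since truncation of an asymmetric tail shifts the COM. COM is invariant to
multiplicative intensity scaling, hence to peak- or area-normalisation.
Averaging requires identical grids — there is deliberately no silent
resampling. Concentration series report mean COM ± sd per mol% and shifts
against the mandatory 0 mol% reference (blue shift negative).

## Bilayer trajectory analysis

Coordinates are Å, frames ordered in time, z along the membrane normal
with the upper leaflet at positive z after centring.

Leaflets and midplane. Phosphorus z values are split per frame by a
two-means partition; the split must be clearly bimodal (inter-group gap >
4× pooled within-group spread), otherwise the input is rejected as not a
bilayer. Frames are shifted so the midpoint of the two leaflet phosphorus
levels is z = 0, and molecules are tagged upper/lower by reference-atom
sign. The midplane is thus defined from the phosphorus levels, not the
mass centre, matching the headgroup definition of the membrane surface.

Density profiles and peaks. Histograms use 0.5 Å bins by default,
normalised per bin volume and frame count. Peak positions are refined by
3-point parabolic interpolation through the peak bin and its neighbours;
the parabola is fitted on log counts when all three are positive — exact
for a Gaussian peak and less biased than a linear-count parabola when the
peak falls between bin centres — falling back to linear counts otherwise.
Thickness is the distance between the refined per-leaflet phosphorus
maxima; with 90 phosphorus atoms per leaflet over 200 frames the estimator
reproduces a known thickness to better than 0.1 Å.

Steroid depth and tilt. The ring centre is the equal-weight centre of the
five scaffold atoms C3, C8, C10, C13, C16 (shared by cholesterol and
progesterone). Tilt is the angle of the C3→C16 axis against the outward
leaflet normal (lower-leaflet vectors sign-corrected), reported on
[0°, 180°] with an optional fold to [0°, 90°] since the folding convention
is not universal; the convention used is recorded on the distribution.

Order parameters. S_CH = ⟨(3cos²θ − 1)/2⟩ over all equivalent C–H bonds,
molecules, leaflets and frames, with θ to the bilayer normal. Explicit
hydrogens are required (all-atom naming; no united-atom reconstruction).
Standard errors come from block averages over 5 consecutive equal frame
segments — appropriate when blocks are longer than the orientational
correlation time; for short trajectories the block error underestimates
the true uncertainty. ΔS_CH profiles subtract a reference carbon-by-carbon
with errors added in quadrature.

Voronoi area per lipid. Each leaflet is tessellated independently from the
projected xy positions of one reference atom per molecule — phosphorus for
phospholipids, the C3-bound oxygen for steroids, both near the lipid–water
interface so the two classes are treated symmetrically. Periodicity is
handled exactly for orthorhombic boxes by 3×3 tiling of the points and
reading the central copies' cells (shoelace areas); per-leaflet cell areas
sum to the box area to ~1e−6 relative, every frame. Coincident projected
points are jittered by 1e−6 Å and flagged.

MSD diffusion. Lateral (xy) MSD averaged over particles and all time
origins, using stored unwrapped coordinates or minimum-image unwrapping of
wrapped ones (valid when no particle moves half a box length between
frames). D = slope/4 from an unweighted linear fit with intercept on the
lag window, default 30–70 ns. MSD is computed at all lags up to
n_frames − 1: restricting lags to half the trajectory would make the
default fit window unusable on a 100-frame run, so the long-lag points
simply carry fewer origins. Estimator precision: for 240 independent
walkers observed for 100 frames, the per-run sd of the fitted D is ~10% —
intrinsic to time-averaged MSD at lags comparable to the trajectory length
(long-lag displacements are strongly correlated across origins) — while
the estimator is unbiased, so means over many runs converge (20 runs: ~2%).
An optional per-frame centre-of-mass drift removal is off by default.

## Synthetic generators: what they emulate and what they do not

The generators produce statistically controlled stand-ins, not physics:

- FRAP traces are the exact model curve plus i.i.d. Gaussian noise on a
  0.1–60 s log-spaced 120-point grid; real traces have correlated noise,
  acquisition bleaching and imperfect bleach profiles.
- Domain images are two-level (dark domains on bright background) with
  optional Gaussian noise and non-overlapping disk/ellipse/blob shapes;
  real images have uneven illumination, partial-volume edges and touching
  domains. Ground-truth areas/perimeters come from dense quadrature of the
  shape outlines.
- Spectra are single Gaussians; Laurdan spectra are asymmetric two-state
  mixtures, so the generator validates COM arithmetic, not band shapes.
- Bilayers are geometric: 90 phospholipids + 30 steroids per leaflet on a
  jittered lattice at the prescribed APL (box side derived as
  √(N·APL)), phosphorus z ~ Normal(±thickness/2, 1 Å), chain carbons on a
  fixed descent with C–H orientations drawn per bond from the two-delta
  mixture {θ=0 w.p. p, θ=90° w.p. 1−p}, p=(2S+1)/3, whose expectation is
  exactly the target S for S ∈ [−0.5, 1]; steroid scaffolds are rigid rods
  with ring-centre depth ~ Normal(8 Å, 0.5 Å) and tilt by mode (upright /
  broad half-normal / fixed angle). Frames are statistically independent —
  there are no dynamics, correlations, or force-field physics, so passing
  round trips validate the estimators, not membrane behaviour.
- Brownian walkers have exact i.i.d. Gaussian increments (variance 2·D·dt
  per axis) generated unwrapped and wrapped afterwards, making the
  4·D·t oracle exact. Defaults (240 particles, 100 frames at 1 ns, box
  89 Å) mirror the simulated-system scale.

Default parameter values are the study conditions: experimental DOPC
diffusion 1.74 µm²/s, simulation diffusion 2.6 µm²/s, bleach radius 5 µm,
thickness 38.3 Å, APL 64 Å², ring depth 8 Å, 50×50 µm images at 0.1 µm/px.
The default S_CH targets are a plausible di-unsaturated-chain profile
(moderate plateau, dip at the C9–C10 double bond, decaying tail) chosen
once as a realistic recovery target.

Problem sizes used in tests and the acceptance script (200-frame bilayers,
20 Brownian seeds, 50 FRAP replicates) were chosen so each estimator's
sampling error sits comfortably inside its stated tolerance.

## Known limitations

- No Gaussian-bleach-profile FRAP variants and no multi-component
  diffusion models.
- No phase identification from morphology and no multi-channel analysis.
- No generalized-polarization (two-band) spectral statistic.
- Trajectory input is multi-frame PDB (GRO single-frame write); compressed
  trajectory formats are out of scope.
- The Voronoi tiling approach assumes orthorhombic boxes.
- Leaflet assignment assumes a planar, non-undulating bilayer; strongly
  curved or pore-containing membranes would defeat the bimodality test.
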
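# Methods

This note documents the models, estimators and numerical choices behind
`fiborient`, in the order data flows through the pipeline.

## Coordinate and angle conventions

Orientation is *axial*: θ and θ + 180° are the same fiber axis, so all
angles live in [0°, 180°), with 0° pointing along the image x-axis
(left→right) and angles increasing counter-clockwise toward +y. Angular
distances use the axial metric min(|Δ| mod 180, 180 − |Δ| mod 180) ∈
[0°, 90°]; means use the doubled-angle circular mean. Geometry z is
depth below the papillary–reticular boundary in µm; slice 0 of a stack
sits at that boundary and depth d = (z_index − boundary_z) × z_interval.

## Synthetic phantom model

The generator emulates the statistical structure of extended reticular
dermis as imaged by multiphoton microscopy, not its optics or
biochemistry.

**Collagen geometry.** Each bundle is a horizontal z-slab (center depth,
thickness) populated with planar sinusoidal centerlines ("crimp"):
position = anchor + s·u(θ) + A·sin(2πs/λ_w + φ)·v(θ), sampled at ≤ 1 µm.
A sinusoid is the simplest periodic crimp model; the defaults
(A = 5 µm, λ_w = 40 µm) are synthetic choices giving an arc/chord ratio
of ≈ 1.15, comfortably below the study stretch of 1.25 — they are not
measured dermal anatomy. Fibers accumulate until the covered area
(Σ chord × diameter per slab layer) reaches `packing_density` (default
0.8) of the tile, which realizes the target within one fiber. Fiber
depth within the slab is Gaussian-concentrated (σ = thickness/5, clipped
to the slab): bundles are lens-shaped rather than flat slabs, so the
degree-of-orientation depth profile is single-peaked per bundle, which is
what derivative-based peak detection presumes.

**Orientation mixture.** Tile orientations follow a 1–3 mode axial
Gaussian mixture (defaults: centers 30°/96°, weights 0.6/0.4, dispersion
10°). Two sampling schemes are provided. With `bundle_coherent=True`
(default) each bundle draws one mode and one bundle orientation
(center + mode dispersion), and its fibers scatter tightly around it
(`within_bundle_jitter_sd`, default 2°): laminar bundles are
orientation-coherent, each contributing one well-defined angle to the
pooled histogram, so mode dispersion acts at the bundle level — the
level at which the mode analysis operates. With `bundle_coherent=False`
every fiber draws its own mode independently, which is the right model
for per-fiber statistics (e.g. mixture-fraction checks) but makes each
bundle an unresolvable blend of modes.

**Elastic network.** Per bundle, a sparse set of mildly undulating
fibers (default 2 µm amplitude) whose orientation is the bundle's
collagen axial mean plus axial Gaussian jitter (default SD 5°); density
is fibers per (100 µm)² per bundle. Elastic diameters default to 4.4 µm
above 200 µm depth and 5.9 µm below, reflecting the thicker deep-dermal
elastic fibers.

**Equibiaxial extension.** The in-plane map (x, y) → (λx, λy) with
z → thickness_factor·z is applied to fiber endpoints; equal in-plane
scaling preserves every chord direction exactly. Each fiber is then
re-crimped along its new chord with the amplitude solved by bisection
(`brentq`, xtol 1e-8) so that its *arc length is conserved* — the fiber
is inextensible and only unbends. The crimp offset is de-trended to
vanish at both endpoints so the rebuilt chord is exactly the affine
image. Once the stretched chord reaches the original arc length the
amplitude clamps to zero (fully straight); beyond that point arc length
grows with the chord. The straightening stretch of a fiber therefore
equals its initial arc/chord ratio, which the mechanics module recovers
independently from stress–strain data. `thickness_factor` defaults to
the incompressibility value 1/λ² (0.64 at λ = 1.25); the empirically
reported 0.6 can be passed instead.

**Rasterization.** Fibers are drawn as Gaussian-profile tubes: polyline
points are splatted onto each slice within ±3σ of their depth (axial
weight Gaussian with σ = diameter/2.355) and blurred with a 2D Gaussian
whose σ combines the tube radius and the in-plane PSF in quadrature, so
a fiber's cross-profile FWHM ≈ √(diameter² + FWHM_PSF²). Amplitude is
normalized so an in-focus fiber core reaches `fiber_intensity`.
Background, Gaussian read noise, clipping and 8-bit quantization follow,
in that order. Points falling outside the tile (e.g. after extension
enlarges the field) are dropped, emulating a fixed imaging window.
Output stacks are (z_extent/z_interval + 1) slices — 251 at defaults.

**What the phantom does not model:** SHG/TPAF contrast physics,
scattering and depth-dependent attenuation, anisotropic 3D PSFs,
out-of-plane fiber tilt, fiber branching and bundle merging, and
viscoelasticity. Passing tests demonstrate the *estimators* recover
planted geometry under realistic sampling and noise; they do not certify
performance on real tissue with those confounds.

**Randomness.** Every generator takes one seed; the pipeline derives
per-tile child seeds deterministically via `numpy.random.SeedSequence`
spawning, and rasterization noise uses a deterministic child of the tile
seed. Same seed ⇒ bit-identical stacks.

## FFT-ellipse orientation estimation

Per slice: optional 2D Hann window (on by default, suppressing the
edge-discontinuity cross), FFT, amplitude (modulus) spectrum with DC
centered. "Amplitude" is the literal reading of averaging spectral
magnitude; squared power is available by squaring upstream. Directional
profile: every sample whose frequency magnitude lies in the annulus
(default periods 3–50 µm, excluding DC/illumination gradients and
near-Nyquist noise) is binned by the direction of its frequency vector
folded to [0°, 180°), 1° bins; the bin value is the mean amplitude, and
each bin also carries its sample count and the standard error of its
mean. Empty bins are filled by circular interpolation and flagged.

The ellipse fit is solved in phase-aligned form. For any origin-centered
ellipse the phase of the second circular harmonic of A(φ) is exactly the
major-axis direction ψ, and 1/A² = u + v·cos 2(φ − ψ) exactly, with
conic eigenvalues u ± |v|; the fiber orientation is the minor axis and
the degree of orientation is √(λ_large/λ_small). The radii fit is a
weighted linear least squares with weights (bin count) × A⁴ — A⁴ makes
it algebraically the same objective as fitting the conic through the
Cartesian points (A cos φ, A sin φ), so the spectral ridge dominates and
an exact ellipse is recovered to machine precision, while solving in the
1/A² domain keeps sharply peaked, non-elliptical profiles (dense
bundles) from driving the conic to a hyperbola. Numerical guards:

- amplitudes floored at 10⁻³ of the profile peak before inversion;
- the anisotropy coefficient v is shrunk by twice its standard error,
  propagated from the per-bin sampling noise of the directional means
  (delta method on 1/A²); |v| ≤ 2·SE flags the slice isotropic
  (degree 1, NaN angle). Per-bin SEMs are capped at their median so
  angular *structure* crossing a bin (a ridge edge) is not mistaken for
  noise. This keeps the pure-noise degree ceiling below the 1.10 peak
  threshold without touching exact model data (SEM = 0);
- the fitted λ_small can overshoot below the data's smallest 1/A² for
  peanut-shaped profiles; it is bounded below by half that minimum, and
  the degree is capped at 1000.

Consequences verified by tests: degree ≥ 1 with equality exactly on the
isotropic flag; rotation equivariance within ±2°; intensity-scale
invariance; degree decreasing monotonically with planted angular
dispersion (5°→45°); agreement with an independent structure-tensor
oracle within 3° on straight-fiber phantoms.

## Depth-peak detection

The degree series is smoothed by a centered moving average (edge-padded)
and peaks are indices where the forward first difference turns from > 0
to ≤ 0, taking the first slice of a plateau. Because smoothing can
displace an apex, each candidate snaps to the raw maximum within the
smoothing support before the importance threshold (raw degree ≥ 1.10) is
applied; candidates snapping to the same index are merged. The default
half-width is 3 slices (7-slice ≙ 14 µm window at the 2 µm z-interval):
per-slice degree speckle on dense stacks decorrelates over roughly the
fiber diameter and fluctuates with a period a 3-slice window cannot
suppress, which over-segments bundles; 14 µm equals one bundle thickness
and stays at least twofold below the 30–44 µm bundle spacings, so
distinct bundles remain resolved. Smoothing is configurable including
off. Peak intervals are reported as mean ± SD of consecutive depth gaps
(NaN sentinel below two peaks). Layers split half-open at 200 µm.

## Collagen–elastic agreement

Both channels run through the same FFT-ellipse estimator. For each
collagen peak, the elastic orientation at the same z-index is paired and
the axial difference binned at 15° over [0°, 90°]. Peaks whose elastic
slice is isotropic are excluded and counted separately rather than
assigned 90°, so unresolvable slices cannot masquerade as disagreement.
Under axial Gaussian jitter with SD 5° the expected fraction ≤ 15° is
2Φ(3) − 1 ≈ 0.997; under independent uniform orientations it is 1/6 —
both are recovered within Monte-Carlo error in the tests.

## Gaussian mode analysis

Pooled bundle orientations are binned on [0°, 180°) (default 10° bins —
fine enough to separate modes ≥ 30° apart, coarse enough for stable
counts at N ≈ 40–600). The histogram is first tested against the uniform
model (Pearson chi-square, dof = bins − 1): if uniformity is not
rejected at α = 0.05 the distribution has no modes to report and the fit
is flagged failed — without this gate, two or three moderate-σ wrapped
Gaussians spaced evenly can approximate the uniform axial density to
below Poisson noise and would pass the goodness-of-fit test vacuously.
Otherwise, for K = 1, 2, 3 a sum of wrapped Gaussians (each evaluated
over its ±180° images; truncation error < 10⁻⁶ for σ < 45°, the upper
bound imposed on σ) is fit by Poisson-weighted nonlinear least squares
(σ_bin = √max(O, 1)), initialized at the K tallest circularly separated
histogram maxima. Model selection takes the smallest K whose Pearson
chi-square (dof = bins − 3K − 1; expected counts floored at 0.5 in the
denominator only, so near-empty tail bins cannot dominate) gives
p ≥ 0.05; if none passes, the best-p fit is returned flagged. Fitted
centers closer than one bin are merged (heights summed, centers
height-weighted axially) before ordering, guarding against one mode
being split. Modes are numbered by descending height; *peak frequency*
is the fitted height at center as a percentage of the total count N
(heights are in counts, so this matches the tabulated-percentage scale
of bundle-frequency reporting). The intermodal angle is the axial
distance between the two tallest centers (NaN sentinel when K = 1,
matching dash entries in per-sample tables); the layer shift is the
axial distance between the two layers' Mode-1 centers.

With N < 30 the fit proceeds but is flagged under-determined.

## Mechanics

Stress is force over the *initial* cross-section (engineering stress, in
MPa for N and mm); strain is displacement over the initial gauge length.
The linear region is identified as the sliding window of length ≥ 30% of
the samples, all of whose stresses lie in the upper half of the stress
range, maximizing OLS R² (ties to the longest window); ε* =
−intercept/slope and λ* = 1 + ε*. The x-intercept is invariant to
uniform force rescaling by construction. The curve generator plants ε*
exactly: an exponential toe a(e^{bε} − 1) joins the line E(ε − ε*) with
C¹ continuity at a knee of 1.25·ε*, and strain runs to 3·ε* so the
eligible upper-stress windows lie wholly in the linear segment —
noiseless recovery is then exact to machine precision. The precondition
that stress peaks at the end of the record is enforced within the last
5% of samples so mildly noisy curves are not rejected.

## Pipeline and problem sizes

The full pipeline synthesizes (or loads) a 3 × 3 tile mosaic, applies the
study protocol of imaging under λ = 1.25 extension (configurable,
including off for resting-state stacks), analyzes both channels, detects
peaks, tallies agreement, pools histograms per layer and fits modes; all
artifacts embed a configuration hash and the run seed. Tests and
examples run reduced rasters (256² pixels, 60–130 µm stacks, 3–9 tiles)
that preserve the pixel pitch regime of the full 512²-pixel, 251-slice
acquisition geometry; the peak-detection acceptance check runs one full
251-slice stack at the native 512² size. These sizes were chosen so the
whole suite exercises every code path at full numerical fidelity while
staying convenient to run repeatedly during development.

## Known limitations

- Orientation is estimated slice-wise in 2D; out-of-plane tilt projects
  and is not recovered.
- The degree of orientation saturates (cap 1000) on near-noiseless dense
  phantoms; on real tissue its useful range is roughly 1–20.
- The crimp model is a planar sinusoid with a single amplitude and
  wavelength per fiber; real crimp is 3D and irregular.
- Mode fitting assumes wrapped-Gaussian shapes with σ < 45°; heavier-
  tailed or skewed angular distributions will select larger K or flag
  failure.
- The isotropy gate makes weakly oriented slices report NaN angles;
  downstream consumers must handle the sentinel (the provided modules
  do).
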
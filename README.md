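# fiborient

Quantitative analysis of collagen and elastic fiber geometry in
multiphoton z-stacks of dermis, with a synthetic phantom generator for
validation.

The reticular dermis is built from tightly packed, wavy (crimped)
collagen fiber bundles organized in horizontal laminae, interwoven with a
sparser elastic-fiber network. Second-harmonic-generation (SHG) imaging
shows the collagen, two-photon autofluorescence (TPAF) the elastin.
Because resting collagen is too densely crimped to resolve, tissue is
imaged under equibiaxial extension (stretch ratio λ = 1.25), which
straightens fibers while preserving their directions. This package
implements the downstream quantitative pipeline for such stacks and is
aimed at researchers quantifying fibrous-tissue architecture (dermis,
tendon, fascia) from calibrated multi-page TIFF z-stacks.

## What it computes

- **Orientation per slice** (`fiborient.orientation`). Each 211 × 211 µm
  slice is Fourier transformed; the mean spectral amplitude per direction
  A(φ) over a frequency annulus (spatial periods 3–50 µm) is fit by an
  origin-centered ellipse. The ellipse's **minor axis** is the fiber
  orientation θ ∈ [0°, 180°) (0° = image left→right, counter-clockwise
  positive, axial); its **axial ratio** ≥ 1 is the *degree of
  orientation* (1 = isotropic).
- **Bundle depth peaks** (`fiborient.peaks`). Collagen bundles appear as
  peaks of the degree-of-orientation depth profile; peaks are found from
  the sign change of the first difference (after moving-average
  smoothing) and peaks with degree < 1.10 are discarded. Depths split
  into superficial (0 ≤ d < 200 µm) and deep (d ≥ 200 µm) reticular
  layers.
- **Collagen–elastic agreement** (`fiborient.compare`). At each collagen
  peak, the axial angular difference to the elastic orientation at the
  same depth, binned at 15° over [0°, 90°].
- **Mode analysis** (`fiborient.modes`). Bundle orientations pooled over
  a 3 × 3 tile mosaic (633 µm region) are decomposed into 1–3 wrapped
  Gaussian modes by Poisson-weighted least squares with chi-square model
  selection; reports mode centers, peak frequencies (% of bundles), the
  intermodal angle between Modes 1 and 2, and the Mode-1 shift between
  layers.
- **Extension similarity** (`fiborient.compare`). Absolute cosine between
  the first principal axes of a fiber network's coordinates before and
  after simulated extension.
- **Mechanics** (`fiborient.mechanics`). Engineering stress–strain curves
  from force–displacement data, and the straightening stretch ratio
  λ* = 1 + ε* from the x-intercept of the best high-stress linear window.
- **Synthetic phantoms** (`fiborient.synthetic`). Ground-truth fiber
  geometries (laminar bundles, axial Gaussian orientation mixtures,
  sinusoidal crimp, co-aligned elastic network), an arc-length-conserving
  equibiaxial extension model, and rasterization to calibrated 8-bit
  TIFF z-stacks.

## Worked example

```bash
python examples/mode_analysis.py
```

```
selected K = 2 modes (chi2 = 3.8, dof = 11, p = 0.976)
  Mode 1: center   29.3°, sigma  10.1°, peak frequency 22.7% of N=600
  Mode 2: center   95.3°, sigma   9.7°, peak frequency 17.3% of N=600
intermodal angle: 66.1°
```

600 bundle orientations drawn from a two-mode axial mixture (centers
30°/96°, weights 0.6/0.4, dispersion 10°) are binned at 10° and fit. The
chi-square test accepts K = 2 (p = 0.98 ≥ 0.05); Mode 1, the taller
peak, recovers the 0.6-weight component near 30°; the intermodal angle
recovers the planted 66° separation — two comparable modes roughly 60–90°
apart indicate a lattice-like rather than single-direction organization.

Other examples under `examples/` cover phantom synthesis, per-slice
orientation profiles, depth-peak detection, collagen–elastic agreement,
extension similarity and the stress–strain straightening point. A thin
CLI mirrors the library:

```bash
fiborient synth --seed 3 --out tile0
fiborient orient --stack tile0/shg.tif --out profile.csv
fiborient peaks --profile profile.csv --out peaks.csv
fiborient run-all --seed 5 --out results_dir
```

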
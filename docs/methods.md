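# Methods

`mdoi` reconstructs a 3D volume of *relative* optical coefficients (absorption
μa, scattering μs) of a turbid, skin-like medium from structured-illumination
reflectance images of its surface. This note documents the models, the
numerical choices, and what the synthetic benchmark does and does not
demonstrate.

## Overview of the method

A projector places isolated illumination points on the sample surface; a
camera records the diffuse halo of re-emitted light around each point. Each
(illumination point, camera pixel) pair is a source–detector pair at
separation ρ. The pipeline is single-step (no iterative inversion):

1. **Acquisition** (synthetic here): Monte-Carlo diffuse reflectance through a
   linear camera model.
2. **Preprocessing**: dark/background subtraction, flat-field division,
   replicate averaging, HDR exposure merging, illumination-point detection,
   patch extraction, intensity→reflectance calibration.
3. **2D fitting**: per pixel, a semi-infinite diffusion model R(ρ; μa, μs′) is
   fitted to cross-sections of the patch, giving 2D coefficient maps.
4. **3D back-projection**: each pair's fitted coefficients are spread over the
   banana-shaped photon-visitation volume for its ρ, weighted and merged.
5. **Uniformity calibration**: division by a featureless reference (or by the
   average patch response of the data itself), giving the relative volume
   from which features are segmented and their depth estimated.

## Photon transport

Weighted-photon Monte Carlo in a voxel grid (`mdoi._kernels`):

- Interaction distances are sampled as optical depth −ln ξ and marched
  face-by-face through voxels, consumed at the local μt = μa + μs
  (incremental DDA; the voxel index is never recomputed from the position).
- At each interaction the photon deposits w·μa/μt and scatters the remainder
  (hop–drop–spin). Henyey–Greenstein phase function with the local g; the
  azimuth is sampled by Marsaglia rejection (no trigonometric calls).
- The z = 0 surface applies stochastic unpolarized Fresnel reflection for the
  internal index mismatch (default n = 1.4 against air); escaped weight is
  tallied in the exit voxel. Specular reflection of the incident beam is not
  simulated: the physical instrument removes it with crossed polarizers, so
  photons are launched with unit weight just below the surface. Lateral and
  bottom faces are absorbing (escape) boundaries; for the 30 × 30 × 10 mm
  dermis block those losses are ≤ 2 × 10⁻³ of the budget.
- Russian roulette below weight 10⁻⁴ with survival probability 0.1. Every
  weight change (deposits, kills, survival amplification) is tallied, so
  reflected + transmitted + side loss + absorbed equals the launched weight
  to ~10⁻¹⁴ relative on every run — the conservation invariant is exact
  bookkeeping, not a statistical statement.
- RNG: per-photon xorshift64* streams derived from (seed, photon index) via
  splitmix64. Results are bit-reproducible for a given (seed, n_photons) and
  independent of execution order.

Validation: for a semi-infinite isotropic medium with single-scattering
albedo 0.9 and matched boundary, the simulated plane albedo at normal
incidence is 0.4140 (4 × 10⁴ photons) against the exact Chandrasekhar
H-function value 0.41495.

The transport assumes a uniform refractive index (per-voxel μa, μs, g are
supported); internal refraction between voxels is out of scope.

## Banana look-up maps

For a homogeneous half-space, the visitation density of paths joining a
surface source to a surface detector at distance ρ is the classic
banana-shaped probability cloud. `build_banana_lut` records each escaped
photon's path segments (midpoint, weight × segment length), rotates the
trajectory so the exit azimuth lands on +x (exact for a homogeneous medium by
in-plane isotropy), and bins it by exit distance into per-ρ 3D grids
(default: one bin per 0.5 mm detector ring out to 8.5 mm; local grid
x ∈ [−4, 12] × y ∈ [−6, 6] × z ∈ [0, 6] mm at the phantom voxel size). Exits
beyond half a bin pitch past the last bin are dropped. Five independent
repetitions are averaged; maps are normalized by total launched photons. Each
bin also stores its *reflectance ratio* — the escaped-weight fraction at that
exit distance — used as the attenuation-aware contribution weight during
back-projection.

The mid-plane visitation centroid sits near ρ/2 for mid-range ρ (2–4 mm);
at larger ρ it is pulled shallower by the weight decay along long paths, a
property of visitation density rather than a numerical artifact.

## Synthetic acquisition and preprocessing

The camera model is linear, 12-bit: counts = gain · exposure · reflectance ·
flatfield + leak + dark + read noise, with Poisson shot noise on the photon
counts. Defaults: gain 10⁴ counts/(ms · unit per-voxel reflectance), dark
offset 100, read noise 2 counts rms, 5% radial flat-field vignetting, 3
counts of projector light leak. These place the halo (per-voxel reflectance
5 × 10⁻² at the source to ~10⁻⁶ at 8 mm) across the exposure ladder
10/20/40/80/160 ms the way a consumer CMOS would see it; 50 replicate frames
per (pattern, exposure) are averaged. The light leak is modeled
exposure-independent so a single all-mirrors-off background frame describes
it; a real projector leak scales with exposure — a deliberate simplification.

HDR merging is Debevec-style for a linear response: per pixel, a
tent-weighted average of value/exposure over non-saturated exposures, the
longest exposure excluded by default (the 10–80 ms merge of a 10–160 ms
acquisition). Pixels saturated everywhere keep the shortest-exposure estimate
and are flagged.

Scanning uses one illumination point per pattern (the zero-cross-talk limit
of spaced multi-point patterns; multi-point patterns are supported by the
generator and the detector). Points are detected as thresholded local maxima
(background mean + 5 σ over the bottom-5% pixels) with brighter-wins
non-maximum suppression; when the pattern design is known the expected point
count caps the detection, which is what the pipeline does.

Reflectance calibration normalizes each patch by its local sum, then fits one
global linear (scale, offset) mapping normalized intensity to the dipole
reflectance of the bulk reference medium. The fit is performed on
half-pixel-ring averages with 1/R weights: the profile spans four decades, so
unweighted least squares would be controlled entirely by the few near-source
pixels and corrupt the far field. The calibrated patches match the dipole
model within ~4% ring-relative RMS for ρ ≥ 1 mm (~3 transport mean free
paths); below that the diffusion approximation itself deviates from
transport by more than 5%, so a tighter round-trip cannot be expected from
any affine calibration.

## Semi-infinite diffusion model and fitting

The closed form is the standard extrapolated-boundary dipole solution:
μt′ = μa + μs′, z₀ = 1/μt′, D = 1/(3μt′), μeff = √(3 μa μt′), z_b = 2AD with
A from the Groenhuis polynomial in the relative index (A(1.4) ≈ 3.25):

R(ρ) = (1/4π) [ z₀ (μeff + 1/r₁) e^{−μeff r₁}/r₁² +
                (z₀ + 2 z_b)(μeff + 1/r₂) e^{−μeff r₂}/r₂² ]

with r₁ = √(ρ² + z₀²), r₂ = √(ρ² + (z₀ + 2 z_b)²).

Accuracy against the Monte Carlo: for an isotropic medium at dermis-like
μs′ = 2.94 mm⁻¹ (n = 1.4) the ring-integrated agreement is within ~11% over
ρ ∈ [2/μs′, 10 mm]. With strongly forward-peaked scattering (g = 0.9 at the
same μs′) the near field deviates up to ~26% below ~2 mm — the similarity
relation μs′ = μs(1−g) breaks down within a few scattering events of the
source — converging to ≤ ~13% beyond. The cross-validation property is
therefore asserted on the isotropic medium; diffusion theory constrains only
μs′, so this is the fair instantiation of the model check.

Fitting is bounded trust-region least squares on log R (the signal spans
decades): initial guess (0.1, 3.0) mm⁻¹, bounds μa ∈ [10⁻⁴, 10],
μs′ ∈ [0.05, 20] mm⁻¹, fitting window from one transport mean free path to
5 mm (half the ~10 mm distance at which the measured signal reaches the
noise floor). The free parameter is the *reduced* μs′; reported μs maps are
μs′/(1−g) with the configured g = 0.9, since the benchmark states full
scattering coefficients. Per pixel, the (ρ, R) pairs of a horizontal and a
vertical band (half-width 1 pixel) through the pixel are fitted independently
and averaged; because the band depends only on the pixel's row or column,
one fit per row and per column covers a patch. Noise-free self-fits recover
both parameters within 1% across μa ∈ [0.01, 1], μs′ ∈ [0.5, 5] mm⁻¹; at 5%
multiplicative noise the median error stays under 10%, with the usual
μa↔μs′ crosstalk (μa, ~100× smaller, is the fragile parameter).

## Back-projection, merging, calibration

Each valid (source, detector) pair adds coefficient × w to the voxel
accumulators and w to the weight accumulator, where w is the banana map of
the nearest ρ bin (no interpolation; bin pitch = detector pitch), rotated to
the pair's azimuth and multiplied by the bin's reflectance ratio. The voxel
estimate is the weighted mean, so a spatially constant coefficient map
reconstructs that constant to machine precision on every sampled voxel. On a
regular detector grid the rotated maps depend only on the integer detector
offset, so they are cached and reused across patches and patterns
(`Backprojector`). Rotation is bilinear resampling about the z axis.

The region of analysis (ROA) is a square of side L centered on the
illumination point; only detectors inside it are used and no voxel deeper
than L/4 is populated — the banana sampling depth is ~ρ/2 and the farthest
usable detector sits L/2 away. Partial patch volumes are realigned to their
source positions and merged by accumulating both sums (weighted averaging).

Uniformity calibration divides the merged volume by a calibration volume —
either a featureless-phantom reconstruction under the same scan, or (default
for the benchmark) *base sampling*: the average of all patch-local partial
volumes, tiled back at the source positions. Division by the common
systematic response removes the radial/depth falloff and the scan-grid
periodicity (the power at the pattern frequency drops by > 100× in the
synthetic regression test). The output is the relative coefficient volume;
a featureless input maps to ≈ 1 everywhere.

MS-SSIM is computed per z slice and averaged. Each scale contributes the
product of the mean luminance, contrast and structure terms (11 × 11
Gaussian window, σ = 1.5, dyadic 2× mean-pooling between scales, all
exponents 1; luminance only at the coarsest scale; the scale count is
capped by what the slice size supports). The stabilization constants
C1 = 6.5, C2 = 58.5, C3 = 29.2 are the standard (0.01 L)², (0.03 L)², C2/2
values for an 8-bit-like dynamic range L = 255, so the metrics report
stretches the unit-scaled volumes to [0, 255] before the comparison —
applied directly to [0,1] data these constants would saturate every term.

Feature segmentation (standing in for the manual segmentation of the
original protocol) thresholds the relative μa volume at mean + k·σ (default
k = 2) and keeps the largest 26-connected component. Reconstructed depth is
the mean depth of the deepest 1% of segmented voxels (voxel-center
convention, position = (index + 0.5)·voxel size).

## The benchmark and the ROA selection rule

The digital benchmark uses the 30 × 30 × 10 mm dermis block
(0.5 × 0.5 × 0.2 mm voxels, μa = 0.04 mm⁻¹, μs = 29.411 mm⁻¹) with a
2 mm-radius pigmented spherical cap (μa = 4.879 mm⁻¹, same μs, melanin-driven
contrast) reaching 0.5, 1 or 3 mm below the surface, plus a buried
2 mm-radius cylinder spanning 1–3 mm. Reduced problem size: a 5 × 5
single-point scan at 4.5 mm pitch, 10⁵ photons per point, LUT built from
5 × 2 × 10⁵ photons. Anisotropy g = 0.9 and index n = 1.4 are typical dermis
values, exposed in the configuration.

A single-step back-projection cannot localize depth sharply: every pair
crossing the feature paints its elevated coefficient along its whole banana,
so the relative volume under a shallow feature stays elevated down to the
depth constraint and the segmented column fills it. Depth readout therefore
follows the method's own ROA selection rule — choose the constraint to just
cover the expected feature depth (side = 4 × depth, with 4 mm as the
practical minimum below which too few detectors remain for the fits). The
benchmark presets use a 4 mm ROA for the 0.5/1 mm features and 12 mm for the
3 mm feature. The qualitative consequence is itself a regression test: an
under-sized ROA pins the reconstructed feature to the bottom of its
constraint, an adequately sized one restores a finite, near-true depth.

## What the synthetic benchmark does not show

- The generator emulates dot illumination, exposure ladders, shot/read
  noise, vignetting and leak — not lens blur, nonlinear response, DMD
  diffraction, sample curvature, ambient drift, or specular breakthrough.
  Passing benchmarks bound algorithmic correctness, not instrument
  performance.
- Absolute coefficient accuracy is not claimed: the output is a relative
  volume; μa/μs′ crosstalk and the near-field model mismatch are absorbed by
  the calibration only to first order.
- The depth estimate inherits the ROA rule's granularity (the constraint is
  an upper bound actively used as the readout); features deeper than the
  SNR-limited ~5 mm are out of reach by design.

## Reduced problem sizes

Defaults in `benchmark_config` / `scripts/acceptance.py` — 25 illumination
points, 10⁵ photons per point, 10⁶ LUT photons — are the package's benchmark
scale, chosen so a full three-case reproduction runs on a laptop-class CPU
in ~15 minutes. All are parameters; scaling photons or grid density up only
tightens the stochastic scatter.
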
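# Methods

`mcdose` reproduces, at desk scale and on synthetic data, a complete
deep-learning denoising workflow for Monte Carlo (MC) radiotherapy dose
distributions: fast MC dose calculations with few particle histories are
cheap but noisy; a 3D U-net maps a high-uncertainty dose distribution
(plus the CT) to the corresponding low-uncertainty one.  This note
documents the models, their assumptions, the numerical choices, and what
the synthetic benchmark does and does not demonstrate.

## Synthetic phantoms and arc plans

Phantoms are ellipsoidal water-equivalent bodies (HU 0) in air
(HU −1000) on a regular grid with 0.25 × 0.25 × 0.25 cm³ voxels, with
optional lung-like (−700 HU) and bone-like (+700 HU) ellipsoidal
inserts.  The body mask is HU > −400; dose is defined as zero outside
it.  Axes are ordered (x, y, z) with z the gantry rotation axis.

Treatment plans are single isocentric VMAT-like arcs: an ordered list of
control points, each with a gantry angle, an MU weight, a rotated
rectangular aperture (the stand-in for an MLC shape — the aperture is an
arc's identity and is never modified by augmentation), a collimator
angle and a nominal energy in {6, 10, 15} MV.  Default arcs have 12
control points spread over a full rotation; source–axis distance is
100 cm.

## Analytic dose engine

The clean (noise-free) dose is an analytic model chosen for arc-like
morphology rather than transport fidelity.  Per control point:

    D(v) ∝ T(u', w') · exp(−μ(E) · d_rad(v)) · (SAD / (SAD + ζ(v)))²

* `T` — the rectangular aperture indicator convolved with an isotropic
  Gaussian penumbra, evaluated in collimator-rotated isocenter-plane
  coordinates (beam divergence projects the transverse coordinates onto
  the isocenter plane).  Penumbra σ = 0.4 / 0.5 / 0.6 cm for
  6 / 10 / 15 MV.
* `exp(−μ d_rad)` — exponential attenuation with radiological depth;
  μ = 0.050 / 0.045 / 0.040 cm²/g, decreasing with energy.  The
  magnitudes are plausible, not commissioning data; only monotone trends
  matter for denoising correctness.
* the inverse-square factor in the depth past the isocenter plane ζ.

Radiological depth inside the engine uses a parallel-beam approximation:
the density grid (linear HU→density map, −1000 → 0, 0 → 1 g/cm³) is
rotated about z so the beam runs along one axis, cumulatively summed,
and rotated back.  This is exact at cardinal gantry angles and agrees
with exact divergent ray marching to better than ~1% at oblique angles
on smooth phantoms; the exact ray-marching routine
(`phantoms.radiological_depth`, step ≤ half the smallest voxel) is kept
as the independent reference and used in tests.  Control points are
summed with MU weights and normalized to Gy/MU.  Dose outside the body
mask is set to exactly zero.

## Noise model

MC dose estimates are non-negative, heteroscedastic, and have per-voxel
relative noise ∝ 1/√N in the particle-history count N, decreasing with
local dose.  We model a noisy realization as

    noisy(v) = clean(v) · g_v,   g_v ~ Gamma(k_v, 1/k_v),
    k_v = k0 · N · clean(v) / max(clean),

i.e. multiplicative unit-mean Gamma noise with per-voxel relative
standard deviation 1/√k_v.  No transport is simulated; only the
statistical structure matters for training the denoiser.

The calibration constant k0 = 2.2 × 10⁻⁶ is fixed so that the
fast-calculation setting the workflow emulates (1.5 × 10⁶ histories)
yields a single-realization statistical uncertainty (SU) above 60% on a
typical arc dose, and the 200× larger reference count (3 × 10⁸) falls
below 5% by the 1/√N law.  SU is reported the conventional way for MC
dose: the mean relative standard error of the mean dose over voxels
above 50% of the maximum, in percent.  (MC dose engines differ in how
they define and report SU; this definition is the common reporting
convention in the MC dose literature and is documented as the package's
choice.)

## Augmentation

A base roster of arcs, each assigned to a phantom (round-robin), is
augmented by an integer factor.  Each variant independently
re-randomizes:

* per-control-point MU weights — multiplicative factors uniform in
  [0.2, 2.0], renormalized to a total MU rescaled by a uniform factor in
  [0.5, 2.0] (the literature leaves the MU randomization range
  unstated; these bounds are the package's choice);
* beam energy — uniform over {6, 10, 15} MV;
* isocenter — uniform shift within ±9 / ±5 / ±10 cm in x / y / z,
  rejection-resampled (up to 100 attempts) until inside the body;
* collimator — a rotation offset uniform in [0°, 360°).

Aperture shapes are never modified.  Every draw is recorded in a roster
that round-trips losslessly through JSON.  Degenerate ranges reproduce
the base arcs exactly, which pins the augmentation logic in tests.

## Network

A standard 3D U-net with two input channels (scaled noisy dose, scaled
CT) and one output channel.  Each resolution level applies two
same-padded 3×3×3 convolutions with ReLU (batch normalization
optional); pooling is 3×3×1 between the first two levels — VMAT arcs
are coplanar and dose gradients along z are comparatively gentle — and
2×2×2 below; upsampling is by learned transposed convolutions whose
stride inverts the corresponding pool; skip connections concatenate at
every level; a final 1×1×1 convolution produces the dose channel.

"Four layers" counts the pooling steps: five resolution levels with the
standard doubling channel ladder 32–64–128–256–512.  This ladder gives
22,578,241 trainable parameters for the production configuration
(two channels, 192×192×64 input, no batch normalization) — 2.2578 × 10⁷
at five significant digits.  The closed-form layer-descriptor count and
the instantiated network's array sizes are verified against each other
for all five candidate configurations (z-size 32/64/96, one or two
channels, with or without batch normalization).

The network, backpropagation and Adam are implemented in NumPy (the
convolutions run as shifted BLAS matrix products; transposed
convolutions with kernel = stride are non-overlapping block expansions).
All gradients are verified against float64 central differences in the
test suite.  Weight initialization is He (fan-in) with a seeded
generator, so construction and training are fully deterministic given
the seed.

## Training protocol

Summed-squared-error loss; batch size 2; Adam at initial learning rate
10⁻⁴; the learning rate is divided by 5 when the validation loss has
not improved for 4 consecutive epochs; training stops after 30 epochs
without improvement; the weights of the best-validation epoch are
returned.  "Improvement" is a strict relative decrease of more than
10⁻⁸ (no tolerance is standard; this one makes the scheduler
deterministic under float noise).  One random patch is drawn per
training triplet per epoch (epoch length = number of training
triplets); patches are augmented by independent mirror coin-flips per
axis and an xy rotation by a random multiple of 90°.  The validation
loss is computed deterministically over full volumes via the patched
inference path.  Splitting is by case (phantom/CT), sizes
round(n · fraction) with at least one case each in validation and test,
so all arc variants of a case share its split.

Intensities are scaled by dataset-level constants: per case, the
maximum of (HU + 1000) for the CT and the maximum dose; the constants
are the means over calibration cases.  At the point of use the pipeline
snaps the applied factor to the nearest power of two: power-of-two
scaling is lossless in floating point, which makes the full
scale → pad → patch → aggregate → restore → unscale chain bit-exact (the
assembly contract below), at the cost of at most a factor √2 deviation
from the calibrated range.

## Inference

Volumes are cropped or zero-padded centrally to the 192-voxel xy
footprint (left-biased by one voxel on odd differences; the placement
record inverts the operation exactly), and covered along z by the
minimal number of patches, the first at 0, the last flush with the top,
the rest equalized; overlapping voxels are averaged with equal weights.
Negative network outputs are clipped to zero and the body mask is
re-applied.  With an identity network the whole chain reproduces the
input bit-exactly on body voxels — this is asserted for z extents 16,
64, 100 and 200.  Whole plans are denoised by summing the per-field
noisy doses and denoising the sum in a single pass.

## Evaluation suite

* **Gamma analysis** (global): dose criterion as a percentage of the
  maximum reference dose, distance-to-agreement in mm, 10%-of-max
  low-dose threshold applied to the reference; the pass-rate denominator
  is the thresholded voxel set.  The search is reference-point-centred
  over the evaluated distribution interpolated trilinearly on a lattice
  of about a tenth of the distance criterion per step, within a search
  radius of 3× the distance criterion, visited in distance-ordered
  vectorized bands with exact finalization (a voxel leaves the search
  when no remaining offset's pure distance term can improve it).  A
  numerical slack of 10⁻⁹ on the γ ≤ 1 decision lets analytically exact
  boundary cases (dose offset equal to the criterion) pass.  An optional
  `gamma_max` cap clamps reported values; any cap ≥ 1 provably leaves
  every pass/fail decision unchanged (a passing voxel's optimum lies
  within one DTA of its reference point) while bounding the search cost
  on grossly failing distributions.  The optimized search is tested
  against an independent exhaustive-search oracle.
* **Masked RMSE** over voxels above 10% of the maximum reference dose,
  in Gy/MU; the whole-treatment translation multiplies by the MU per
  fraction and the number of fractions (prescription / fraction dose).
* **ISNR** = 10·log₁₀(MSE(noisy, ref) / MSE(denoised, ref)) over the
  body mask, in dB; exact agreement with the reference is signalled as
  an unbounded-improvement condition rather than returned as a number.
* **DVH**: cumulative curves at 0.01 Gy bins; Dx% read off the curve
  with linear interpolation (clamped to the observed dose range), Vx%
  as the fraction of the structure at or above a dose level, Dm the
  structure mean.

## Benchmark scale and what it shows

The acceptance benchmark trains a narrow-width replica of the
architecture (channel ladder 8–16–32–64–128, 48-voxel xy footprint,
z-patch 16) on 60 synthetic triplets (15 base arcs × factor 4 on ten
48³ phantoms), 15 epochs at the full protocol, fixed seed.  On held-out
cases this model reaches a median ISNR above 10 dB — the denoised
distribution is an order of magnitude closer (in MSE) to the clean
reference than the noisy input.  These problem sizes are the package's
benchmark conditions; larger runs only improve the margins.

Passing these tests shows that the full chain — simulator statistics,
training protocol, patched inference, metrics — is implemented
correctly and that the denoising approach works on data with MC-like
noise structure.  It does not show clinical performance: the phantoms
are convex and homogeneous-ish, the dose engine has no scatter,
build-up, or MLC leaf structure, and the noise is exactly the model the
network trains against.  Published clinical figures for this workflow
depend on real CTs, a real MC engine and a full-scale training run, and
are out of scope here.

### A note on gamma and noisy distributions

One directional surrogate sometimes proposed for denoising benefit —
"the noisy input's gamma pass rate against the clean reference should be
lower than the denoised output's" — is not attainable under interpolated
global gamma with voxel-independent noise, and the corresponding
acceptance check in this suite is expected to fail: the distance-to-
agreement search interpolates the evaluated distribution, and between
two statistically independent noisy voxels the interpolant sweeps a wide
dose range, so a crossing of the reference value almost always exists
within the search radius.  At the benchmark's noise level the noisy
input consequently scores ≈99.9% under 3%/3 mm — above anything a real
denoiser can reach — even though its RMSE is ~4× worse and its ISNR
~12 dB worse than the denoised result.  This insensitivity of gamma to
noise in the *evaluated* distribution is a known property of the metric,
which is why the accompanying ISNR and RMSE checks, not gamma, carry the
denoising-benefit claim.

## Known limitations

* The analytic engine's parallel-beam radiological depth ignores beam
  divergence in the attenuation term (exact at the isocenter plane).
* Gamma assumes a common grid for reference and evaluated volumes and a
  voxel-aligned fine lattice; arbitrary-grid pairs must be resampled
  first (the integral-conserving resampler is suitable).
* Conservative resampling is separable per axis; it preserves the total
  integral to ≤10⁻⁶ relative but is not the exact multi-dimensional
  conservative remap of the original gridding algorithm it stands in
  for.
* Batch normalization uses per-batch statistics with batch size 2 when
  enabled, with known accuracy caveats; the selected configuration does
  not use it.
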
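# Methods

`hardigen` studies whether the second half of a single-shell HARDI
acquisition can be predicted from the first half, and what that prediction
buys downstream: diffusion profiles and tractography computed from the
*completed* dataset (measured + predicted volumes) are compared against
the full acquisition, alongside the half acquisition alone.  Because no
clinical cohort ships with the package, every experiment runs on synthetic
crossing-fiber phantoms with known ground truth; this note records the
models, defaults, and the reasoning behind the open design choices.

## Acquisition model and gradient schemes

A scheme is an ordered list of unit gradient directions with b-values; MPG
index 0 is the unweighted (b0) image.  Directions are designed by
minimizing the antipodal electrostatic energy

    E = sum_{i<j} 1/|d_i - d_j| + 1/|d_i + d_j|

with projected gradient descent on the sphere (step-halving line search,
restarts from random initializations, best energy wins).  The optimizer is
deterministic for a fixed seed, and its energy is non-increasing by
construction of the line search.  Checks worth knowing: n=3 converges to
orthogonal axes, n=6 to the icosahedral arrangement (minimum folded angle
63.43°), and n=64 — the acquisition emulated throughout — reaches the same
energy (within 1%) from independent restart batches, with a minimum folded
angle around 17°.  The emulated acquisition is b = 3000 s/mm², 64
directions plus one b0, 2.5 mm isotropic voxels.  Schemes serialize to FSL
bvec/bval and JSON.

Splitting at k keeps the b0 axes with the first part (network input is b0
plus the first 32 directions; the remaining 32 are the teaching data).

## Phantom generator

Phantoms are multi-tensor crossing-fiber volumes.  Each bundle is a
straight tube (polyline centerline, radius in voxels) carrying an axially
symmetric tensor with eigenvalues (1.7, 0.3, 0.3)×10⁻³ mm²/s — typical
white-matter values producing realistic attenuation at b = 3000.  The
noiseless signal is

    S(g,b) = S0 [ Σ_k f_k exp(-b gᵀ D_k g) + f_bg exp(-b d_iso) ]

with isotropic background d_iso = 0.8×10⁻³ mm²/s.  Two modeling points:

- **Support region.** Signal exists only inside a centered sphere (radius
  0.46 of the smallest grid extent); outside it is air.  Without this the
  b0 image is spatially constant and the b0-derived analysis mask — used
  for every similarity metric — is undefined.
- **Overlap fractions.** Bundles carry volume fraction 1; where bundles
  overlap, per-voxel fractions are renormalized to sum to one, so a
  two-bundle crossing is an equal 0.5/0.5 mixture while single-bundle
  voxels remain pure tensors (which is what makes exact DTI recovery
  testable there).

Rician noise is applied per channel as sqrt((S+n₁)² + n₂²) with
n₁,n₂ ~ N(0, σ²).  The sample mean at S = 0 equals σ√(π/2), which the test
suite verifies by Monte Carlo.  Dataset generation randomizes crossing
angle (50–90°), in-plane orientation (0–180°), sub-voxel center offsets
(±2 voxels), and tube radius (3–4.5 voxels); the default datasets are
noiseless, since scanner preprocessing (denoising, distortion and motion
correction) is outside the package's scope and the study conditions call
for clean, controlled inputs.  Noise is available through configuration,
and its main DTI-level effect is characterized in the tests (mean FA bias
about −0.03 in single-fiber voxels at σ = 0.02·S0).

Default grids are 32³ voxels — large enough for a crossing plus background
but desk-scale; the clinical 96×96×60 matrix is reachable via config.

## Network

The predictor maps 33 input channels (b0 + first 32 MPG volumes) to 32
output channels on the same grid.  It is an encoder–decoder with, per
level, a 3³ same-resolution convolution, stride-2 3³ convolutions for
downsampling, transposed convolutions (stride 2) for upsampling,
concatenation skip connections, ReLU activations, and a linear 1×1×1
output head.  Two choices were genuinely open and decided as follows:

- **Input skip.** The input volumes are concatenated onto the finest
  decoder features right before the output head.  The dominant part of the
  angular-completion map is voxelwise and nearly linear (resampling the
  attenuation profile at new directions), and the long skip lets the head
  represent that component directly instead of forcing it through the
  encoder bottleneck; in practice this cut convergence time by several
  fold on CPU.
- **Width/depth.** Default 3 levels, 8 base filters (~94k parameters).
  This is the smallest configuration that resolves crossing geometry on
  32³ phantoms while training whole-volume on one CPU in minutes; widths
  and depths are configurable, and the reported parameter count equals the
  closed-form layer-by-layer count for any configuration.

Training minimizes the mean squared error between prediction and the
measured second half with Adam.  Volumes are intensity-normalized by a
robust b0 maximum (99th percentile over the foreground); the scale is
recorded and inverted before any metric is computed.  The desk profile
uses minibatch 2, 40 epochs, learning rate 10⁻² with cosine decay to 2% —
small batches give more optimizer steps per epoch at identical cost (the
trainer accumulates per-sample gradients), and the decaying rate is what
reaches the ≥100× loss reduction the acceptance suite demands within the
epoch budget.  Training is deterministic given the seed; the
best-validation-epoch weights are restored at the end.  Predictions are
clamped at zero because DWI signals are magnitudes.

The network and its gradients are implemented directly in NumPy (im2col
convolutions assembled per kernel offset, adjoint-based transposed
convolutions).  The test suite pins the backward pass to central
differences: exactly for each linear primitive, and end-to-end with the
activation replaced by identity so that ReLU's nondifferentiability cannot
contaminate the check.

## Three evaluation arms

For every held-out phantom: arm (a) is the measured b0+32 dataset, arm (b)
appends the 32 predicted volumes, arm (c) appends the 32 measured volumes
(the reference).  Arm (b) and (c) carry 65 channels and identical schemes;
arm (a) carries the first-half scheme.  All comparisons are (a vs c) and
(b vs c); the headline question is whether (b) sits closer to (c) than (a)
does.

## Reconstruction

**DTI** is a weighted log-linear least-squares fit (weights = squared
observed signals), eigen-decomposed per voxel; negative eigenvalues are
clamped to zero and flagged.  FA uses the standard normalized eigenvalue
dispersion; E1 is the principal diffusivity in mm²/s (values around
0.7×10⁻³ in the phantom mixtures; any µm²/ms-style display scaling is
cosmetic).  On noiseless single-tensor voxels the fit recovers ground
truth eigenvalues to ~10⁻¹¹ mm²/s.

**Q-ball** uses the analytic Funk–Radon transform: the normalized signal
E = S/S0 is expanded in the real, orthonormal, even-order SH basis with
Laplace–Beltrami regularization (weight 0.006, the conventional analytic
QBI choice), and the transform multiplies each order by 2π·P_l(0).  An
independent oracle in the tests integrates the SH-expanded signal over
great circles numerically and matches the diagonal route to ~10⁻¹⁴.
Whether the original toolchain used numerical rather than analytic Q-ball
is unknowable from its outputs; this package standardizes on the analytic
form.

**GQI** evaluates the spin distribution function
SDF(u) = Σ_i S_i sinc-kernel(σ√(6D₀b_i)·(g_i·u)) on the sample hemisphere
(σ = 1.25 by default, D₀ the free-water diffusivity fixed by the constant
6D₀ = 0.01506 mm²/s) and projects it to SH so the same divergence and peak
machinery applies.  The SDF is linear in the signal; an isotropic
free-water voxel is flat to max/min < 1.01 (at the phantom's slower
background diffusivity the kernel side-lobes leave ~1.1% ripple).

**SH order policy.**  The largest even l with (l+1)(l+2)/2 ≤ number of
directions, capped at 8: arm (a) reconstructs at lmax 6, arms (b) and (c)
at lmax 8.  For coefficient-space comparisons across arms, lower-order
sets are zero-padded into the lmax-8 layout.

**Sample sphere.**  Spherical functions are evaluated on 181 hemisphere
points obtained by folding a frequency-6 geodesic icosahedron (362 near
equal-area vertices; minimum folded angle 9.3°).  Sampling then re-fitting
at the same order reproduces SH coefficients to 10⁻⁶, so the point set is
adequate for lmax 8.

**Peaks.**  Local maxima on the sampled hemisphere (strictly greater than
all angular neighbors), thresholded at 0.5 of the per-voxel maximum,
greedily separated by ≥25°, at most 3 per voxel.  Two numerical guards:
functions whose sampled spread is below 10⁻⁶ of their maximum are treated
as flat (no peaks) so machine-noise ripples on isotropic voxels cannot
spawn directions; and retained peaks are refined by re-evaluating the SH
function on a denser (frequency-16) hemisphere within a ~10° cap, which
brings single-fiber peak error from the ~5° coarse-grid quantization down
to under 2.5°.

## Metrics

- **JSD** between two sampled spherical functions, each clamped at zero
  and normalized to a 181-bin probability vector; natural log, so values
  sit in [0, ln 2].  Zero bins are floored at 10⁻¹² inside the divergence
  (clamped ODF samples can be exactly zero); with 181 bins of typical mass
  ~5×10⁻³ the floor perturbs reported values far below the precision
  quoted anywhere.
- **ACC**: cosine similarity of SH coefficient vectors with the l=0 term
  excluded; undefined (NaN, excluded from averages) when either
  anisotropic part vanishes, as in pure-background voxels.
- **SSIM** per MPG axis with a 3D Gaussian window (σ=1.5, 11³ support,
  k₁=0.01, k₂=0.03), dynamic range from the reference maximum over the
  mask, averaged over the b0-derived mask.  Against scikit-image's
  volumetric SSIM the implementation agrees to 10⁻⁴.
- **PSNR** = 10·log₁₀(MAX²/MSE) over the mask, +∞ for identical inputs.
- **DSC** = 2|x∩y|/(|x|+|y|) of voxelized bundles.
- **Paired statistics**: Wilcoxon signed-rank (exact for n ≤ 12 after
  dropping zero differences), effect size r = |Z|/√N; three-arm FA/E1
  comparisons use Friedman plus pairwise Wilcoxon at the
  Bonferroni-corrected threshold 0.0167.

The analysis mask is derived from the b0 image (Otsu threshold, largest
connected component, one-voxel closing; a fraction-of-max mode exists for
degenerate histograms).  Voxelwise JSD/ACC are averaged within that mask;
per-case means feed the paired tests.

## Tractography

Deterministic Euler streamlines in voxel coordinates: step 0.5 voxel,
turning limit 45° per step, minimum length 4 voxels, one seed per seed
voxel at the voxel center, both directions, nearest-voxel peak lookup
choosing the peak best aligned (after antipodal folding) with the incoming
direction.  Termination reasons (mask exit, no peak, angle) are recorded
per streamline.  Phantom ROIs mirror the seed/target/avoidance protocol of
tract-of-interest studies: the seed is one end-slab of a bundle, the
target the other end-slab, and an optional mid-plane avoidance ROI can be
configured.  Streamlines must reach the target and must not touch the
avoidance ROI; empty results are flagged as non-visualized bundles and the
affected bundle is excluded pairwise from DSC comparisons, with the
exclusion count reported.  Voxelization marks every voxel a segment
traverses (3D digital differential analyzer), verified in the tests
against an exhaustive segment–box oracle.  Bundle masks compare against
arm (c)'s mask via DSC.  Streamlines export to TrackVis .trk through
nibabel (the affine maps voxel centers to mm).

## Problem sizes and reproducibility

The package's experiment profile is deliberately desk-scale: 20 training,
2 validation and 5 test phantoms at 32³, the compact U-net, 40 epochs —
the full pipeline runs in minutes on one CPU, and all acceptance
properties are asserted at these sizes.  All randomness flows from one
master seed through named per-stage seeds (scheme design, dataset, weight
initialization, shuffling); reports serialize with sorted keys and no
timestamps, and rerunning a config byte-identically reproduces the report
JSON.

## What the phantom results do and do not show

Passing tests demonstrate that the implementation is internally correct
(oracle-pinned metrics, exact parameter recovery, deterministic plumbing)
and that the study design behaves qualitatively as intended on clean
geometry: completed datasets track the full acquisition more closely than
half datasets in JSD/ACC, and bundle overlap is maintained or improved.
They do not demonstrate clinical performance: real brains add anatomy-
scale heterogeneity, preprocessing residuals, Rician noise, and pathology,
and the half-acquisition arm is far stronger on two-bundle phantoms than
on real crossing anatomy.  Absolute clinical numbers (SSIM, JSD, ACC, DSC
on patient cohorts) are therefore out of reach by construction, and the
package makes no attempt to match them.

## Known limitations

- Straight-tube bundles only; curvature appears in tracking only through
  the angular-threshold mechanics, not in the generator defaults.
- Single-shell signal model; no multi-shell schemes or models.
- The NumPy network trains whole-volume; no patch pipeline or GPU path.
- Peak refinement is grid-based (≈2° quantization), not a continuous
  optimizer.
- Exact Wilcoxon p-values switch to the normal approximation above n=12,
  with midrank handling of ties and no continuity correction in the
  effect-size Z.
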
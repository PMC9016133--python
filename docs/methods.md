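# Methods

This note documents the models, conventions, parameter choices and known
limitations of `cardiodti`. Everything quantitative stated here is computed
by the test suite or by `scripts/acceptance.py`.

## Signal model and tensor estimation

The diffusion-weighted signal is modelled as monoexponential
(Stejskal–Tanner): `S_i = S0 · exp(−b_i g_iᵀ D g_i)`. The tensor is
estimated per voxel by least squares on `log(S_i/S0)` using the weighted
frames only; `S0` is the arithmetic mean of the b = 0 frames. OLS is the
default; WLS (weights `S_i²`, the first-order variance stabilisation of the
log transform) is available and gives marginally lower angle noise at low
SNR. Non-positive signals are floored at `1e-6·S0` before the log and the
voxel is flagged (`clipped_signal`). Negative eigenvalues are reported and
flagged, never clipped — FA is still computed from the raw eigenvalues so QC
can see implausible voxels. Eigenvector signs are arbitrary; every consumer
(angles, tractography) is sign-invariant, which the tests assert explicitly.

The fit requires ≥ 6 weighted directions of full design rank and ≥ 1
reference frame; all-b0 or coplanar direction sets are rejected at model
construction with the rank named.

## The synthetic left ventricle

The phantom emulates the acquisition geometry the pipeline targets: 0.1 mm
isotropic voxels (default 64³ grid), two b = 0 references and 12 diffusion
directions at b_max = 933 s/mm². The 12-direction scheme is not published
for the target protocol, so a frozen electrostatic-repulsion table ships as
package data (design-matrix condition number 1.61); other direction counts
fall back to a deterministic Fibonacci hemisphere.

Geometry is a truncated prolate ellipsoidal shell — apex closed, base open —
with default endocardial/epicardial semi-axes (1.0, 4.2) / (2.2, 5.0) mm:
a wall ~1.2 mm thick at the equator, mouse-like at the default grid.
Geometries thinner than 2 voxels anywhere are rejected. `PhantomSpec.for_grid(n)`
scales the shell to smaller grids for cheap tests.

Microstructure truth: the helix angle varies linearly with transmural depth
from `ha_endo` (+60° default) to `ha_epi` (−60°), E1 lies in the wall-tangent
plane (exactly orthogonal to the local radial axis), E2 sits in the
cross-myocyte plane at the prescribed sheetlet angle `e2a_true` (0° default;
recovery analyses use 20°, a realistic magnitude), and eigenvalues default to
(1.0, 0.7, 0.5)×10⁻³ mm²/s — plausible for fixed tissue; only their ratios
matter for FA and angles. Relaxation effects are not modelled; `s0` absorbs
them (tensor estimation is invariant to global scale). Near the long axis
(ρ < 2 voxels) the circumferential direction is undefined; those voxels are
excluded from the truth validity mask.

**Transmural coordinate.** The truth depth is anchored at the *expected
contour-voxel-center radii* — half a voxel inside the analytic interfaces —
because that is the coordinate any contour-based estimator measures; with
this convention the estimator and the truth agree to ~0.02 across the wall
and prescribed endpoint values are recoverable. On the apical cap (slices
without a cavity cross-section) the truth falls back to the same 3D
contour-distance ratio the geometry stage uses.

**Noise.** Rician: the magnitude of a complex Gaussian perturbation with
σ = s0/snr_b0, applied to every voxel including the signal-free background
(as in real magnitude images; the background mean tends to σ√(π/2), which a
Monte-Carlo test checks). `snr_b0 = inf` returns the exact forward model.
Identical specs (including `rng_seed`) produce bit-identical volumes.

**Cohorts.** `sample_cohort_specs` adds subject-level variability: helix
endpoints and sheetlet angle jittered with SD 2°, all eigenvalues scaled by
a shared log-normal factor with SD 3%. Inter-animal variation is
subject-level and shared across segments, which is what makes per-cell group
tests behave like they do on real cohorts (strongly correlated cells).
Group effects are injected by scaling all three eigenvalues in one
region × layer cell (e.g. basal subepicardium × 0.85 — an MD effect that
leaves FA and angles untouched).

The cohort analyses are run at `e2a_true = 20°` rather than the 0° phantom
default: at the 0° fold the |E2A| estimator's noise-floor bias is maximal
and coupled to signal amplitude, so a pure-MD group effect would leak into
|E2A| through the estimator rather than through the tissue model — a
degenerate configuration real myocardium does not occupy.

## Denoising

Overcomplete local PCA: 5×5×5 patches (configurable) across all frames,
eigenvalues of each patch covariance thresholded by a Marchenko–Pastur
criterion — the largest tail of t eigenvalues whose own mean σ̂² bounds its
edge by σ̂²(1+√(t/N))² is treated as noise — and every voxel's overlapping
patch estimates averaged. A fixed `sigma` can replace the per-patch
estimate. The procedure is deterministic, operates on magnitude data, and
applies no Rician bias correction. On noiseless input the tail eigenvalues
are numerically zero, so the transform is the identity to ~1e-8 relative
RMS; at SNR 25 it roughly halves the signal RMSE and cuts the helix-angle
RMSE of the downstream fit by about a third (computed in the acceptance
script). It refuses stacks with fewer than 7 frames (no separable noise
bulk) and patches that do not exceed the frame count.

## LV geometry

Contours are extracted per short-axis slice (4-connectivity): endocardial =
wall voxels adjacent to the cavity, epicardial = wall voxels adjacent to the
exterior. Each endocardial voxel is paired to its nearest epicardial voxel
in-slice; the profile length plus one in-plane voxel (half per side,
center-to-interface correction) is the wall thickness. An ideal annulus of
inner radius 10 and outer radius 15 voxels at 0.1 mm yields 0.5 mm on all
profiles.

Depth uses the in-slice distance-ratio rule `d_endo/(d_endo + d_epi)` on the
two contour distance transforms — 0 on the endocardial contour, 1 on the
epicardial contour, monotone along straight profiles; a `nearest_profile`
rule is available. Slices with only one contour are skipped with a warning;
their wall voxels (and the apical cap) get the 3D analogue.

Layers split at mid depth (tie at exactly 0.5 → subepicardial, a documented
arbitrary choice). Note the volumes are *not* equal on a thick-walled
ventricle: the mid-depth surface of the default phantom puts ~38–41% of wall
voxels in the subendocardial layer, a geometric necessity, not an artifact.

Regions split the wall-bearing slices into equal thirds along the long axis
(base = the end the long-axis vector points to; the phantom uses grid +z,
`"auto"` uses the mask's principal axis). AHA segments: 6 sectors of 60° in
base and mid, 4 of 90° apically, counted from a configurable reference angle
(the phantom has no right-ventricular landmark to anchor segment 1, so
analyses aggregate to base/mid/apex × layer); apical slices without a cavity
form segment 17.

Local frames: radial = normalized in-slice gradient of the depth map
(extended 0 in the cavity / 1 outside and smoothed by 1 voxel before
differentiation to suppress voxelization ripple); longitudinal = long axis
orthogonalized against radial; circumferential = l × r (right-handed).
Voxels with gradient < 0.05/mm (flat depth — no wall thicker than 20 mm is
plausible) or a collapsed orthogonalization are flagged and excluded from
angle maps. Contour voxelization leaves ~2° of azimuthal ripple in the
radial axis; that ripple tilts the frame about the longitudinal axis and
perturbs helix angles only at second order — voxelwise HA recovery on the
noiseless phantom is ~0.003° median.

## Angle maps and aggregation

HA and |E2A| follow the conventions in the README (positive HA =
right-handed helix, toward the base). Voxels whose projection norm is below
0.2 (near-radial fiber, ill-conditioned angle) are flagged invalid and
excluded; the validity threshold is deliberately conservative.

Transmural profiles report HA at 0/25/50/75/100% of the wall; voxels are
binned to the nearest sampling depth (half-width 0.125). The bin value is a
*local linear fit evaluated at the target depth* (with one MAD-trimmed
refit) rather than a plain mean: for a constant field the two coincide, but
at the one-sided 0%/100% bins a plain mean is biased a half-bin inward
(~7.5° on a ±60° wall), and the trim protects against the small apical
cluster whose transmural coordinate is poorly defined. The plain mean is
available via `estimator="mean"`.

The region × layer table reports mean/median/SD per metric over
(base, mid, apex, global) × (subendo, subepi, global); counts refer to the
wall mask so cells partition the wall exactly, and global rows are computed
from pooled voxels (hence voxel-weighted by construction).

## Tractography

Deterministic streamlines, Euler integration at half-voxel steps,
nearest-neighbor direction lookup by default (axial eigenvector fields
interpolate poorly through sign flips; trilinear lookup with sign alignment
is available). Seeds are uniform over mask voxels with a sub-voxel uniform
offset, from a fixed seed. The per-step direction sign is aligned with the
previous step. Continuation requires staying in the mask, FA ≥ threshold
(0.075 default) and turning < 60°/step (the angular-coherence default; the
protocol this emulates does not quantify it). Tract length is
(points − 1) × step; tracts below the minimum bundle length (0.1 / 1 mm
defaults) are dropped. Tractograms are written as TCK plus a per-tract TSV
(length, length-weighted mean HA — equal steps make that the point mean)
and a JSON count summary.

Tract helix statistics classify each tract by the sign of its mean HA, with
the region taken at the seed. On the anatomically shaped phantom the
positive-tract proportion is well below 0.5 (~0.2–0.3): the outer
(negative-HA) half of a thick wall simply holds more volume and the apical
cap is depth-skewed. The 50/50 symmetry property holds — and is tested — on
a flat-slab helix field where the two halves are genuinely equal.

## Statistics

Per metric × region × layer cell (≥ 3 subjects per group required):
Shapiro–Wilk on each group at α = 0.05; both normal → unpaired two-tailed
t-test; otherwise (including one non-normal group or a zero-spread group)
exact two-sided Mann–Whitney U. Both groups constant and equal → P = 1 with
a degenerate flag. No multiple-testing correction is applied; the cell count
is reported so users can apply their own. Fully separated 5-vs-5 samples
give the exact two-sided P = 2/252 ≈ 0.0079, cross-checked in the tests by
enumerating all 252 rank configurations.

The type-I error of the gated rule is measured on 200 replicate 5-vs-5 null
cohorts drawn from a normal subject-level model calibrated to the mean/SD of
a phantom cohort's cell — the object under test is the decision rule, and a
parametric subject-level model is the appropriate null for it (simulating
2,000 full image pipelines would test the same rule at vastly higher cost).
The measured rate is ~0.04–0.07 at α = 0.05.

## Pipeline

`run_pipeline` executes phantom → (denoise) → fit → geometry → metrics →
track from one config; dependencies are validated before anything runs,
unknown config keys are rejected, a resolved config copy and a SHA-256
manifest are written, and one global seed fans out to per-stage seeds by
stable hashing so toggling one stage never changes another's randomness.

## Problem sizes

Recovery analyses run on the 64³ phantom (the emulated acquisition's
resolution at a desk-friendly field of view); cohort simulations use 48³
subjects (10 full pipeline runs per comparison), chosen as the smallest
grid at which all region × layer cells stay well populated.

## Limitations

* The phantom has no right ventricle, papillary muscles, trabeculation, or
  epicardial fat; no T1/T2, fixation chemistry, or k-space/EPI artifacts;
  noise is spatially uniform. Passing recovery tests demonstrates the
  correctness of the analysis chain, not robustness to segmentation error
  or real-tissue heterogeneity.
* The denoiser is a standard spectral-cutoff local PCA, not a numerical
  replication of any particular published implementation.
* Contours are inputs (or phantom truth); no endo/epi segmentation from raw
  images is attempted.
* Single-shell DTI only — no multi-shell or kurtosis models.
* The AHA segment reference angle is a free parameter in the absence of an
  RV landmark; per-segment results are reproducible but their numbering is
  conventional.
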
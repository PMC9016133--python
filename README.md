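# cardiodti

Ex vivo cardiac diffusion-tensor MRI (DT-MRI) microstructure analysis for
small-animal hearts: diffusion tensor fitting, left-ventricular (LV)
layer/segment geometry, helix- and sheetlet-angle mapping, transmural
profiles, deterministic fiber tractography, and normality-gated two-group
statistics — together with a synthetic LV phantom that makes every stage of
the pipeline verifiable by parameter recovery.

## Who this is for

High-resolution DT-MRI of fixed rodent hearts is used to ask whether a
disease model remodels the myocardium's water diffusion properties (mean
diffusivity, fractional anisotropy) and/or its fiber architecture (the
counter-directional transmural helix of myocyte bundles, the orientation of
myolaminar sheetlets). Scanned cohorts are small, the post-processing chain
is long, and each stage — denoising, tensor estimation, wall geometry,
eigenvector projections, tractography, statistics — can silently bias the
result. This package implements that chain as a tested library with a CLI,
and ships a generator of hollow-LV phantoms with exactly known
microstructure so the chain's accuracy can be measured rather than assumed.

## The model

Each diffusion-weighted frame follows the monoexponential Stejskal–Tanner
signal equation per voxel,

    S_i = S0 · exp(−b_i · g_iᵀ D g_i),

with b-value `b_i` (s/mm²), unit gradient direction `g_i`, and the symmetric
3×3 diffusion tensor `D` (mm²/s). `D` is estimated by least squares on
log-attenuation (OLS default, WLS optional) from 2 reference (b = 0) frames
and 12 directions at b = 933 s/mm², then eigendecomposed into
λ1 ≥ λ2 ≥ λ3 with eigenvectors E1, E2, E3. Scalar maps:

* MD = (λ1 + λ2 + λ3)/3
* FA = √(3/2) · √(Σᵢ (λᵢ − MD)² / Σᵢ λᵢ²)

Microstructure angles use a per-voxel local frame (c, l, r) =
(circumferential, longitudinal, radial) built from the transmural depth map
(0 at the endocardium, 1 at the epicardium):

* **Helix angle (HA)**: signed angle from c to the projection of E1 onto the
  wall-tangent plane span(c, l), positive toward the base, folded to
  [−90°, 90°] (fibers are axial). Healthy myocardium runs from positive HA
  at the subendocardium to negative HA at the subepicardium.
* **Sheetlet angle |E2A|**: unsigned angle in [0°, 90°] from the
  cross-myocyte direction m = r × ê1 to the projection of E2 into the
  cross-myocyte plane span(m, r).

Tractography integrates streamlines bidirectionally along ±E1 (Euler, half-
voxel steps) from 10,000 random in-wall seeds, continuing while FA ≥ 0.075,
the tract stays in the LV mask, and the turning angle stays below 60°/step;
tracts shorter than the minimum bundle length (0.1 or 1 mm) are discarded.

Group comparisons follow a normality-gated rule per metric × region × layer
cell: Shapiro–Wilk on each group at α = 0.05; both normal → unpaired
two-tailed t-test, otherwise exact two-sided Mann–Whitney U.

## Worked example

```python
import numpy as np
from cardiodti import (PhantomSpec, build_phantom, DiffusionTensorModel,
                       build_geometry, helix_angle, transmural_profile)

# 64^3 phantom at 0.1 mm: hollow LV wall, helix +60 deg (endo) to -60 deg
# (epi), acquisition of 2 b=0 frames + 12 directions at b = 933 s/mm^2,
# Rician noise at SNR 50
spec = PhantomSpec.for_grid(64, snr_b0=50.0, rng_seed=42)
dwi, gtab, truth = build_phantom(spec)

fit = DiffusionTensorModel(dwi, gtab, mask=truth.myocardium).fit()
print(fit.summary())

geom = build_geometry(truth.myocardium, truth.cavity, truth.affine)
ha = helix_angle(fit.primary_eigenvector, geom.frames, geom.frame_valid)
profile = transmural_profile(ha, geom.depth, geom.region_labels)
print(profile[profile.region == "LV"].to_string(index=False))
```

prints

```
Diffusion tensor fit
====================
method:               ols
voxels fitted:        42496
weighted directions:  12
b=0 frames:           2
b_max (s/mm^2):       933
negative eigenvalues: 0 voxels
clipped signals:      0 voxels
MD  (mm^2/s): median 7.3357e-04  IQR [7.2018e-04, 7.4672e-04]
FA:           median 0.3356  IQR [0.3152, 0.3560]

region  depth_pct  mean_ha_deg  n_voxels
    LV        0.0    59.002965      4160
    LV       25.0    29.895355      7856
    LV       50.0     0.057949     10348
    LV       75.0   -29.979807     11392
    LV      100.0   -59.145420      8892
```

The recovered MD sits at the phantom's prescribed mean eigenvalue
(0.733×10⁻³ mm²/s), FA at the prescribed anisotropy (0.330), and the 5-point
transmural helix profile recovers the prescribed +60° → −60° linear helix to
about a degree despite the noise.

The same chain is available from a shell:

```bash
cardiodti phantom --grid 64 --snr-b0 50 --out-dir run/
cardiodti fit --dwi run/dwi.nii.gz --bval run/dwi.bval --bvec run/dwi.bvec \
              --mask run/myocardium.nii.gz --out-dir run/
cardiodti run --config pipeline.yaml     # full phantom→...→track pipeline
```

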
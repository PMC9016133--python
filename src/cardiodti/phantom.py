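"""Synthetic left-ventricle phantom with known microstructure.

The phantom is a truncated prolate ellipsoidal shell (apex closed, base open)
mimicking a fixed mouse left ventricle: default grid 64x64x64 at 0.1 mm
isotropic, wall ~1.2 mm thick at the equator.  Within the wall the primary
diffusion eigenvector follows a counter-directional helical field — helix
angle varying linearly with transmural depth from ``ha_endo`` at the
endocardium to ``ha_epi`` at the epicardium — and the secondary eigenvector
sits in the cross-myocyte plane at a prescribed sheetlet angle.  Simulated
acquisitions follow the ex vivo protocol the pipeline targets: two b=0
reference frames plus 12 diffusion directions at b = 933 s/mm^2, with Rician
noise at a configurable SNR.

Every generated quantity (depth, helix angle, sheetlet angle, tensors, masks,
layer/region labels, local frames) is returned exactly in a
:class:`GroundTruth` so downstream estimators can be scored by parameter
recovery.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import binary_dilation, distance_transform_edt

from .io import DWIVolume, GradientTable

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "build_phantom",
    "simulate_dwi",
    "gradient_directions",
    "default_gradient_table",
    "sample_cohort_specs",
]

REGION_NONE, REGION_BASE, REGION_MID, REGION_APEX = 0, 1, 2, 3
LAYER_NONE, LAYER_SUBENDO, LAYER_SUBEPI = 0, 1, 2

REGION_NAMES = {REGION_BASE: "base", REGION_MID: "mid", REGION_APEX: "apex"}
LAYER_NAMES = {LAYER_SUBENDO: "subendo", LAYER_SUBEPI: "subepi"}

#: reference LV extent (mm) the default ellipsoid radii are drawn for.
_REFERENCE_EXTENT = 6.4


def gradient_directions(n: int) -> np.ndarray:
    """Return ``n`` unit diffusion directions.

    The 12-direction case ships as a frozen electrostatic-repulsion table
    (the acquisition layout this pipeline emulates does not publish its
    directions, so the scheme is a package convention).  Other counts fall
    back to a deterministic Fibonacci hemisphere.
    """
    if n == 12:
        ref = importlib.resources.files("cardiodti.data") / "directions12.txt"
        dirs = np.loadtxt(str(ref))
        return dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
    if n < 6:
        raise ValueError(f"need >= 6 directions for a tensor fit, got {n}")
    i = np.arange(n) + 0.5
    z = i / n  # upper hemisphere only: directions are axial
    phi = i * math.pi * (3.0 - math.sqrt(5.0))
    rho = np.sqrt(1.0 - z**2)
    return np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=1)


def default_gradient_table(
    n_directions: int = 12, b_max: float = 933.0, n_b0: int = 2
) -> GradientTable:
    """Acquisition layout: ``n_b0`` b=0 frames then ``n_directions`` at b_max."""
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_directions, float(b_max))])
    bvecs = np.concatenate(
        [np.zeros((n_b0, 3)), gradient_directions(n_directions)], axis=0
    )
    return GradientTable(bvals=bvals, bvecs=bvecs)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic LV and its simulated acquisition.

    Geometry is a pair of coaxial ellipsoids of revolution about the grid
    z-axis, centred laterally, with the shared centre on the (open) base
    plane; the wall is the shell between them, truncated at the base and
    closed at the apex.  All lengths in mm, angles in degrees, diffusivities
    in mm^2/s.
    """

    grid_shape: tuple = (64, 64, 64)
    voxel_size: float = 0.1
    a_endo: float = 1.0   # endocardial equatorial radius
    c_endo: float = 4.2   # endocardial semi-length (base->apex)
    a_epi: float = 2.2    # epicardial equatorial radius
    c_epi: float = 5.0    # epicardial semi-length
    base_z: float | None = None  # base-plane z (mm); default 4 voxels below top
    ha_endo: float = 60.0
    ha_epi: float = -60.0
    e2a_true: float = 0.0
    eigenvalues_true: tuple = (1.0e-3, 0.7e-3, 0.5e-3)
    s0: float = 1000.0
    snr_b0: float = math.inf
    rng_seed: int = 0
    n_directions: int = 12
    b_max: float = 933.0
    n_b0: int = 2
    #: {(region name, layer name): factor} scaling all three eigenvalues in
    #: that cell, e.g. {("base", "subepi"): 0.85} — used to build group effects.
    region_scale: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        l1, l2, l3 = self.eigenvalues_true
        if not (l1 >= l2 >= l3 > 0):
            raise ValueError(
                f"eigenvalues must satisfy l1 >= l2 >= l3 > 0, got {self.eigenvalues_true}"
            )
        for name in ("ha_endo", "ha_epi"):
            v = getattr(self, name)
            if not -90.0 <= v <= 90.0:
                raise ValueError(f"{name} = {v} outside [-90, 90] degrees")
        if not (self.a_endo < self.a_epi and self.c_endo < self.c_epi):
            raise ValueError("endocardial radii must lie inside epicardial radii")
        if self.n_directions < 6:
            raise ValueError(
                f"{self.n_directions} directions underdetermine the tensor (need >= 6)"
            )
        if self.n_b0 < 1:
            raise ValueError("need at least one b=0 reference frame")

    @classmethod
    def for_grid(cls, n: int, **overrides) -> "PhantomSpec":
        """Default mouse-LV geometry scaled to an n^3 grid at 0.1 mm."""
        voxel = overrides.get("voxel_size", 0.1)
        f = n * voxel / _REFERENCE_EXTENT
        params = dict(
            grid_shape=(n, n, n),
            a_endo=1.0 * f,
            c_endo=4.2 * f,
            a_epi=2.2 * f,
            c_epi=5.0 * f,
        )
        params.update(overrides)
        return cls(**params)

    @property
    def affine(self) -> np.ndarray:
        return np.diag([self.voxel_size] * 3 + [1.0])

    def resolved_base_z(self) -> float:
        if self.base_z is not None:
            return self.base_z
        return (self.grid_shape[2] - 1) * self.voxel_size - 3.0 * self.voxel_size

    def slice_radii(self, z_mm: np.ndarray):
        """Inner/outer wall radii (mm) per slice height; NaN where absent."""
        h = np.asarray(z_mm, dtype=float) - self.resolved_base_z()
        with np.errstate(invalid="ignore"):
            r_in = self.a_endo * np.sqrt(1.0 - (h / self.c_endo) ** 2)
            r_out = self.a_epi * np.sqrt(1.0 - (h / self.c_epi) ** 2)
        r_in = np.where((h <= 0) & (np.abs(h) < self.c_endo), r_in, np.nan)
        r_out = np.where((h <= 0) & (np.abs(h) < self.c_epi), r_out, np.nan)
        return r_in, r_out


@dataclass
class GroundTruth:
    """Exact (pre-noise) microstructure and geometry of a phantom.

    ``valid`` marks wall voxels whose local frame — hence helix/sheetlet
    truth — is well defined (the near-axis apical core is excluded).
    """

    ha: np.ndarray             # degrees, NaN outside wall / invalid
    abs_e2a: np.ndarray        # degrees
    tensors: np.ndarray        # (..., 6): Dxx, Dyy, Dzz, Dxy, Dxz, Dyz
    eigenvalues: np.ndarray    # (..., 3) descending, after regional scaling
    depth: np.ndarray          # transmural depth in [0, 1], NaN outside wall
    myocardium: np.ndarray     # bool wall mask
    cavity: np.ndarray         # bool LV blood-pool mask
    layer_labels: np.ndarray   # int8, LAYER_* codes
    region_labels: np.ndarray  # int8, REGION_* codes
    frames: np.ndarray         # (..., 3, 3): rows c, l, r
    valid: np.ndarray          # bool: frames/angles defined
    affine: np.ndarray
    long_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def tensors_full(self) -> np.ndarray:
        """Tensors as symmetric (..., 3, 3) matrices."""
        return tensor6_to_matrix(self.tensors)


def tensor6_to_matrix(t6: np.ndarray) -> np.ndarray:
    t6 = np.asarray(t6)
    out = np.zeros(t6.shape[:-1] + (3, 3), dtype=t6.dtype)
    out[..., 0, 0] = t6[..., 0]
    out[..., 1, 1] = t6[..., 1]
    out[..., 2, 2] = t6[..., 2]
    out[..., 0, 1] = out[..., 1, 0] = t6[..., 3]
    out[..., 0, 2] = out[..., 2, 0] = t6[..., 4]
    out[..., 1, 2] = out[..., 2, 1] = t6[..., 5]
    return out


def matrix_to_tensor6(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m)
    return np.stack(
        [m[..., 0, 0], m[..., 1, 1], m[..., 2, 2],
         m[..., 0, 1], m[..., 0, 2], m[..., 1, 2]],
        axis=-1,
    )


def _region_thirds(wall: np.ndarray) -> np.ndarray:
    """Base/mid/apex labels from equal thirds of wall-bearing slices.

    Base is the high-z end (the long axis points apex->base along +z).
    """
    labels = np.zeros(wall.shape, dtype=np.int8)
    zs = np.flatnonzero(wall.any(axis=(0, 1)))
    zs_desc = zs[::-1]  # base first
    thirds = np.array_split(zs_desc, 3)
    for code, sl in zip((REGION_BASE, REGION_MID, REGION_APEX), thirds):
        for z in sl:
            labels[..., z][wall[..., z]] = code
    return labels


def build_phantom(spec: PhantomSpec):
    """Generate a phantom acquisition with exact ground truth.

    Returns
    -------
    (DWIVolume, GradientTable, GroundTruth)

    Raises
    ------
    ValueError
        If the wall is anywhere thinner than 2 voxels, or the direction
        count underdetermines the tensor (checked by :class:`PhantomSpec`).
    """
    nx, ny, nz = spec.grid_shape
    v = spec.voxel_size
    zc = spec.resolved_base_z()
    cx = (nx - 1) / 2.0 * v
    cy = (ny - 1) / 2.0 * v

    x = np.arange(nx) * v - cx
    y = np.arange(ny) * v - cy
    z = np.arange(nz) * v - zc
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    rho = np.hypot(X, Y)

    f_in = (rho / spec.a_endo) ** 2 + (Z / spec.c_endo) ** 2
    f_out = (rho / spec.a_epi) ** 2 + (Z / spec.c_epi) ** 2
    below_base = Z <= v / 2.0
    cavity = (f_in < 1.0) & below_base
    wall = (f_out <= 1.0) & (f_in >= 1.0) & below_base

    # minimum wall thickness: in-slice annulus width where a cavity exists,
    # axial extent of the apical cap otherwise
    z_mm = np.arange(nz) * v
    r_in, r_out = spec.slice_radii(z_mm)
    both = np.isfinite(r_in) & np.isfinite(r_out)
    min_thickness = min(
        float(np.nanmin(r_out[both] - r_in[both])) if both.any() else np.inf,
        spec.c_epi - spec.c_endo,
    )
    if min_thickness < 2.0 * v:
        raise ValueError(
            f"wall thickness {min_thickness:.3f} mm is thinner than 2 voxels "
            f"({2 * v:.3f} mm); enlarge the shell or refine the grid"
        )

    # --- transmural depth ---------------------------------------------------
    # Anchored at the expected contour-voxel-center radii (half a voxel inside
    # the analytic interfaces), the same coordinate a discrete contour-based
    # depth estimator measures; clipped to [0, 1] at the border voxels.
    depth = np.full(spec.grid_shape, np.nan)
    has_cavity = cavity.any(axis=(0, 1))
    rin_z = np.where(np.isfinite(r_in), r_in, 0.0) + v / 2.0
    rout_z = np.where(np.isfinite(r_out), r_out, np.inf) - v / 2.0
    denom = rout_z - rin_z
    cav_slices = has_cavity & (denom > 0) & np.isfinite(denom)
    d_slice = (rho - rin_z[None, None, :]) / np.where(
        cav_slices[None, None, :], denom[None, None, :], np.nan
    )
    in_cav_slice = wall & cav_slices[None, None, :]
    depth[in_cav_slice] = np.clip(d_slice[in_cav_slice], 0.0, 1.0)

    cap = wall & ~in_cav_slice
    if cap.any():
        # apical cap (no in-slice cavity): 3D distance ratio between the
        # discrete endo/epi contour voxel sets, the same construct a
        # contour-based depth estimator falls back to there
        struct = np.zeros((3, 3, 3), dtype=bool)
        struct[:, 1, 1] = struct[1, :, 1] = True  # in-slice 4-connectivity
        outside = ~(wall | cavity)
        endo_c = wall & binary_dilation(cavity, structure=struct)
        epi_c = wall & binary_dilation(outside, structure=struct)
        d_in = distance_transform_edt(~endo_c, sampling=v)
        d_out = distance_transform_edt(~epi_c, sampling=v)
        with np.errstate(invalid="ignore"):
            d_cap = d_in / (d_in + d_out)
        depth[cap] = np.clip(d_cap[cap], 0.0, 1.0)

    # --- local frames (c, l, r) and helix field -----------------------------
    # radial: in-slice outward horizontal unit vector (same convention the
    # geometry stage recovers); degenerate near the long axis.
    valid = wall & (rho > 2.0 * v)
    with np.errstate(invalid="ignore", divide="ignore"):
        r_hat = np.stack([X / rho, Y / rho, np.zeros_like(X)], axis=-1)
    r_hat[~valid] = np.array([1.0, 0.0, 0.0])
    l_hat = np.broadcast_to(np.array([0.0, 0.0, 1.0]), r_hat.shape).copy()
    c_hat = np.cross(l_hat, r_hat)

    ha_true = np.full(spec.grid_shape, np.nan)
    ha_all = spec.ha_endo + depth * (spec.ha_epi - spec.ha_endo)
    ha_true[valid] = ha_all[valid]

    ha_rad = np.where(np.isfinite(ha_all), np.deg2rad(ha_all), 0.0)
    e1 = (
        np.cos(ha_rad)[..., None] * c_hat + np.sin(ha_rad)[..., None] * l_hat
    )
    m = np.cross(r_hat, e1)  # cross-myocyte direction: in tangent plane, ⊥ e1
    e2a_rad = math.radians(spec.e2a_true)
    e2 = math.cos(e2a_rad) * m + math.sin(e2a_rad) * r_hat
    e3 = np.cross(e1, e2)

    abs_e2a = np.full(spec.grid_shape, np.nan)
    abs_e2a[valid] = abs(spec.e2a_true)

    # --- labels and regional eigenvalue scaling -----------------------------
    region_labels = _region_thirds(wall)
    layer_labels = np.zeros(spec.grid_shape, dtype=np.int8)
    layer_labels[wall & (depth < 0.5)] = LAYER_SUBENDO
    layer_labels[wall & (depth >= 0.5)] = LAYER_SUBEPI

    evals = np.zeros(spec.grid_shape + (3,))
    evals[wall] = np.asarray(spec.eigenvalues_true)
    for (region, layer), factor in spec.region_scale.items():
        rcode = {v: k for k, v in REGION_NAMES.items()}[region]
        lcode = {v: k for k, v in LAYER_NAMES.items()}[layer]
        cell = (region_labels == rcode) & (layer_labels == lcode)
        evals[cell] *= float(factor)

    tensors_mat = (
        evals[..., 0, None, None] * e1[..., :, None] * e1[..., None, :]
        + evals[..., 1, None, None] * e2[..., :, None] * e2[..., None, :]
        + evals[..., 2, None, None] * e3[..., :, None] * e3[..., None, :]
    )
    tensors_mat[~wall] = 0.0
    tensors = matrix_to_tensor6(tensors_mat)

    frames = np.stack([c_hat, l_hat, r_hat], axis=-2)

    gtab = default_gradient_table(spec.n_directions, spec.b_max, spec.n_b0)
    s0_map = np.where(wall, spec.s0, 0.0)
    dwi = simulate_dwi(
        tensors, gtab, s0_map, spec.snr_b0, spec.rng_seed,
        affine=spec.affine, sigma_reference=spec.s0,
    )

    truth = GroundTruth(
        ha=ha_true,
        abs_e2a=abs_e2a,
        tensors=tensors,
        eigenvalues=evals,
        depth=depth,
        myocardium=wall,
        cavity=cavity,
        layer_labels=layer_labels,
        region_labels=region_labels,
        frames=frames,
        valid=valid,
        affine=spec.affine,
    )
    return dwi, gtab, truth


def simulate_dwi(
    truth_tensors,
    gtab: GradientTable,
    s0,
    snr_b0: float,
    rng_seed: int = 0,
    affine=None,
    sigma_reference: float | None = None,
) -> DWIVolume:
    """Forward-simulate a DWI acquisition from a tensor field.

    The monoexponential signal model ``S = S0 * exp(-b g' D g)`` is evaluated
    per frame; at finite ``snr_b0`` the magnitude of a complex Gaussian
    perturbation is taken (Rician noise) with ``sigma = S0_ref / snr_b0``.
    At ``snr_b0 = inf`` the forward model is returned exactly.

    Parameters
    ----------
    truth_tensors : (..., 6) or (..., 3, 3) array
        Diffusion tensors, mm^2/s.
    s0 : scalar or array
        Reference (b=0) signal; an array allows a zero background.
    sigma_reference : float, optional
        S0 value defining the noise level when ``s0`` is a map
        (defaults to its maximum).
    """
    t = np.asarray(truth_tensors, dtype=float)
    if t.shape[-2:] == (3, 3):
        t6 = matrix_to_tensor6(t)
    elif t.shape[-1] == 6:
        t6 = t
    else:
        raise ValueError(f"tensor array must be (...,6) or (...,3,3), got {t.shape}")

    b = gtab.bvals
    g = gtab.bvecs
    norms = np.linalg.norm(g[~gtab.b0_mask], axis=1)
    if norms.size and np.any(np.abs(norms - 1.0) > 1e-6):
        raise ValueError("gradient directions must be unit-norm")

    # b * g' D g per frame, from the 6 unique components
    design = np.stack(
        [g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
         2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2], 2 * g[:, 1] * g[:, 2]],
        axis=1,
    ) * b[:, None]
    atten = np.exp(-np.tensordot(t6, design, axes=([-1], [1])))  # (..., n_frames)
    s0_arr = np.asarray(s0, dtype=float)
    signal = s0_arr[..., None] * atten if s0_arr.ndim else s0_arr * atten

    if math.isfinite(snr_b0):
        if snr_b0 <= 0:
            raise ValueError("snr_b0 must be positive")
        ref = sigma_reference
        if ref is None:
            ref = float(s0_arr.max()) if s0_arr.ndim else float(s0_arr)
        sigma = ref / snr_b0
        rng = np.random.default_rng(rng_seed)
        n_re = rng.standard_normal(signal.shape)
        n_im = rng.standard_normal(signal.shape)
        signal = np.hypot(signal + sigma * n_re, sigma * n_im)

    if affine is None:
        affine = np.diag([0.1, 0.1, 0.1, 1.0])
    return DWIVolume(data=signal, affine=affine)


def sample_cohort_specs(
    base_spec: PhantomSpec,
    n_subjects: int,
    rng_seed: int,
    ha_jitter_deg: float = 2.0,
    e2a_jitter_deg: float = 2.0,
    diffusivity_jitter: float = 0.03,
    region_scale: dict | None = None,
) -> list:
    """Draw per-subject phantom specs with subject-level variability.

    Inter-subject variation is modelled at the whole-heart level — helix
    endpoints and the sheetlet angle jittered by their SDs (degrees) and all
    eigenvalues scaled by a common log-normal factor with SD
    ``diffusivity_jitter`` — so that, as in real cohorts, a subject's
    regional metrics share one biological offset.  ``region_scale`` applies
    a group effect (e.g. basal subepicardial eigenvalues x0.85) on top.
    """
    rng = np.random.default_rng(rng_seed)
    specs = []
    for _ in range(n_subjects):
        scale = float(np.exp(rng.normal(0.0, diffusivity_jitter)))
        evals = tuple(l * scale for l in base_spec.eigenvalues_true)
        ha_e = float(np.clip(base_spec.ha_endo + rng.normal(0, ha_jitter_deg), -90, 90))
        ha_p = float(np.clip(base_spec.ha_epi + rng.normal(0, ha_jitter_deg), -90, 90))
        e2a = float(np.clip(base_spec.e2a_true + rng.normal(0, e2a_jitter_deg), -90, 90))
        specs.append(
            replace(
                base_spec,
                eigenvalues_true=evals,
                ha_endo=ha_e,
                ha_epi=ha_p,
                e2a_true=e2a,
                rng_seed=int(rng.integers(0, 2**31 - 1)),
                region_scale=dict(region_scale or {}),
            )
        )
    return specs
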
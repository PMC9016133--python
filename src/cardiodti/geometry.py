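"""Left-ventricular anatomical scaffold.

From a myocardial wall mask and the LV cavity (blood-pool) mask this module
derives everything the microstructure analysis needs:

* endocardium→epicardium *profiles* — each endocardial contour voxel paired
  with its closest epicardial contour voxel in the same short-axis slice —
  whose lengths give the local wall thickness;
* a transmural *depth* map, 0 at the endocardial contour and 1 at the
  epicardial contour;
* the subendocardial/subepicardial *layer* split at mid depth;
* base / mid-cavity / apex *regions* (equal thirds of wall-bearing slices
  along the long axis) and the AHA 17-segment labelling;
* a per-voxel local orthonormal frame (circumferential, longitudinal,
  radial) for eigenvector projections.

Slices are taken perpendicular to the grid z-axis; data whose long axis is
not aligned with z should be resampled first (`estimate_long_axis` gives the
principal axis of the wall mask for that purpose).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation, distance_transform_edt, gaussian_filter
from scipy.spatial import cKDTree

from .phantom import (
    LAYER_SUBENDO,
    LAYER_SUBEPI,
    REGION_APEX,
    REGION_BASE,
    REGION_MID,
    REGION_NAMES,
)

__all__ = [
    "LVGeometry",
    "build_profiles",
    "split_layers",
    "assign_regions",
    "local_frames",
    "build_geometry",
    "estimate_long_axis",
]

logger = logging.getLogger(__name__)

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)  # 4-connectivity


def _slice_contours(wall2d: np.ndarray, cavity2d: np.ndarray):
    """Endo/epi contour voxels of one short-axis slice.

    The endocardial contour is the set of wall voxels 4-adjacent to the
    cavity; the epicardial contour is the set of wall voxels 4-adjacent to
    the exterior (neither wall nor cavity).
    """
    outside = ~(wall2d | cavity2d)
    endo = wall2d & binary_dilation(cavity2d, structure=_CROSS)
    epi = wall2d & binary_dilation(outside, structure=_CROSS)
    return endo, epi


def estimate_long_axis(mask: np.ndarray) -> np.ndarray:
    """Principal axis of a mask (unit vector, oriented toward +z)."""
    pts = np.argwhere(mask).astype(float)
    pts -= pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts, full_matrices=False)
    axis = vt[0]
    if axis[2] < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def build_profiles(
    myocardium: np.ndarray,
    cavity: np.ndarray,
    affine: np.ndarray,
    depth_method: str = "distance_ratio",
):
    """Endo→epi profiles, wall thickness, and the transmural depth map.

    Every endocardial contour voxel is connected to the closest epicardial
    contour voxel within its slice (Euclidean distance in mm); the profile
    length is the wall thickness there.  Because contour voxel *centers* sit
    about half a voxel inside the tissue interfaces, half an in-plane voxel
    is added at each end so the reported thickness estimates the continuum
    wall width.  Off-profile wall voxels receive a depth by the
    ``depth_method`` rule:

    ``distance_ratio`` (default)
        depth = d_endo / (d_endo + d_epi) from in-slice distance transforms
        of the two contour sets — 0 on the endocardial contour, 1 on the
        epicardial one, monotone along straight profiles.
    ``nearest_profile``
        distance to the endocardial contour divided by the thickness of the
        nearest profile.

    Slices with an endocardial but no epicardial contour (or vice versa) are
    skipped with a logged warning; wall voxels in skipped or cavity-free
    slices (the apical cap) fall back to the 3D analogue of the rule.

    Returns
    -------
    depth : float array
        Transmural depth in [0, 1], NaN outside the wall.
    profiles : pandas.DataFrame
        One row per profile: slice index, endo/epi voxel indices and
        ``thickness_mm``.
    """
    if depth_method not in ("distance_ratio", "nearest_profile"):
        raise ValueError(f"unknown depth_method {depth_method!r}")
    myocardium = np.asarray(myocardium, dtype=bool)
    cavity = np.asarray(cavity, dtype=bool)
    if not myocardium.any():
        raise ValueError("empty myocardium mask")
    vox = np.linalg.norm(np.asarray(affine)[:3, :3], axis=0)
    in_plane = vox[:2]

    nz = myocardium.shape[2]
    endo_all = np.zeros_like(myocardium)
    epi_all = np.zeros_like(myocardium)
    rows = []
    depth = np.full(myocardium.shape, np.nan)
    covered = np.zeros_like(myocardium)

    for k in range(nz):
        wall2d = myocardium[..., k]
        if not wall2d.any():
            continue
        endo, epi = _slice_contours(wall2d, cavity[..., k])
        if endo.any() != epi.any():
            logger.warning(
                "slice %d has only one contour (endo=%s, epi=%s); skipped",
                k, bool(endo.any()), bool(epi.any()),
            )
            continue
        if not endo.any():
            continue  # cavity-free slice (apical cap): handled by 3D fallback
        endo_all[..., k] = endo
        epi_all[..., k] = epi

        endo_pts = np.argwhere(endo)
        epi_pts = np.argwhere(epi)
        tree = cKDTree(epi_pts * in_plane)
        dist, idx = tree.query(endo_pts * in_plane)
        dist = dist + in_plane.mean()  # center-to-interface correction
        for (i, j), d, m in zip(endo_pts, dist, idx):
            rows.append(
                {
                    "slice": k,
                    "i_endo": int(i),
                    "j_endo": int(j),
                    "i_epi": int(epi_pts[m, 0]),
                    "j_epi": int(epi_pts[m, 1]),
                    "thickness_mm": float(d),
                }
            )

        wall_idx = np.argwhere(wall2d)
        if depth_method == "distance_ratio":
            d_endo = distance_transform_edt(~endo, sampling=in_plane)
            d_epi = distance_transform_edt(~epi, sampling=in_plane)
            with np.errstate(invalid="ignore"):
                d2 = d_endo / (d_endo + d_epi)
            depth[wall_idx[:, 0], wall_idx[:, 1], k] = d2[wall2d]
        else:
            etree = cKDTree(endo_pts * in_plane)
            dist_e, nearest = etree.query(wall_idx * in_plane)
            thick = np.asarray(dist)[nearest]  # thickness of nearest profile
            with np.errstate(divide="ignore", invalid="ignore"):
                d2 = np.clip(dist_e / np.maximum(thick, in_plane.min()), 0.0, 1.0)
            depth[wall_idx[:, 0], wall_idx[:, 1], k] = d2
        covered[..., k] = wall2d

    if not rows:
        raise ValueError("no slice contains both an endo and an epi contour")

    remaining = myocardium & ~covered
    if remaining.any():
        d_endo3 = distance_transform_edt(~endo_all, sampling=vox)
        d_epi3 = distance_transform_edt(~epi_all, sampling=vox)
        with np.errstate(invalid="ignore"):
            d3 = d_endo3 / (d_endo3 + d_epi3)
        depth[remaining] = d3[remaining]

    depth[myocardium & endo_all] = 0.0
    depth[myocardium & epi_all & ~endo_all] = 1.0
    return depth, pd.DataFrame(rows)


def split_layers(depth: np.ndarray) -> np.ndarray:
    """Subendo/subepi labels from the mid-wall split (depth 0.5 → subepi)."""
    labels = np.zeros(depth.shape, dtype=np.int8)
    wall = np.isfinite(depth)
    labels[wall & (depth < 0.5)] = LAYER_SUBENDO
    labels[wall & (depth >= 0.5)] = LAYER_SUBEPI
    return labels


def assign_regions(
    myocardium: np.ndarray,
    cavity: np.ndarray,
    long_axis=(0.0, 0.0, 1.0),
    reference_angle: float = 0.0,
):
    """Base/mid/apex regions and AHA 17-segment ids.

    Wall-bearing slices are split into equal thirds along the long axis
    (base = the end the long-axis vector points to).  Circumferentially,
    basal and mid slices are divided into 6 sectors of 60° and apical slices
    into 4 sectors of 90°, counted counter-clockwise from
    ``reference_angle`` (degrees, about the slice centroid); apical slices
    without a cavity cross-section form the apical cap (segment 17).

    Returns (region_labels, segment_ids), both int8/int16 voxel maps.
    """
    myocardium = np.asarray(myocardium, dtype=bool)
    long_axis = np.asarray(long_axis, dtype=float)
    zs = np.flatnonzero(myocardium.any(axis=(0, 1)))
    if len(zs) < 3:
        raise ValueError(f"need >= 3 wall-bearing slices, got {len(zs)}")
    zs_base_first = zs[::-1] if long_axis[2] >= 0 else zs
    thirds = np.array_split(zs_base_first, 3)

    region_labels = np.zeros(myocardium.shape, dtype=np.int8)
    segment_ids = np.zeros(myocardium.shape, dtype=np.int16)
    region_of_slice = {}
    for code, sl in zip((REGION_BASE, REGION_MID, REGION_APEX), thirds):
        for k in sl:
            region_of_slice[int(k)] = code
            region_labels[..., k][myocardium[..., k]] = code

    ref = np.deg2rad(reference_angle)
    for k, code in region_of_slice.items():
        wall2d = myocardium[..., k]
        if not wall2d.any():
            continue
        if code == REGION_APEX and not cavity[..., k].any():
            segment_ids[..., k][wall2d] = 17  # apical cap
            continue
        pts = np.argwhere(wall2d)
        ci, cj = pts.mean(axis=0)
        theta = np.arctan2(pts[:, 1] - cj, pts[:, 0] - ci) - ref
        theta = np.mod(theta, 2 * np.pi)
        if code == REGION_BASE:
            seg = 1 + (theta // (np.pi / 3)).astype(int) % 6
        elif code == REGION_MID:
            seg = 7 + (theta // (np.pi / 3)).astype(int) % 6
        else:
            seg = 13 + (theta // (np.pi / 2)).astype(int) % 4
        segment_ids[pts[:, 0], pts[:, 1], k] = seg
    return region_labels, segment_ids


def local_frames(
    depth: np.ndarray,
    myocardium: np.ndarray,
    affine: np.ndarray,
    long_axis=(0.0, 0.0, 1.0),
    cavity: np.ndarray | None = None,
    smooth_voxels: float = 1.0,
):
    """Per-voxel local (circumferential, longitudinal, radial) frames.

    The radial axis is the normalized in-slice gradient of the transmural
    depth (pointing endo→epi); the longitudinal axis is the long-axis
    direction orthogonalized against it; the circumferential axis completes
    the right-handed triad c = l x r.  The depth field is extended (0 in the
    cavity, 1 outside) and smoothed by ``smooth_voxels`` before
    differentiation to suppress voxelization ripple.

    Returns
    -------
    frames : (..., 3, 3) array
        Rows are c, l, r.
    valid : bool array
        False where the gradient is degenerate (flat depth) or the
        orthogonalization collapses; such voxels are excluded from angle
        maps downstream.
    """
    myocardium = np.asarray(myocardium, dtype=bool)
    long_axis = np.asarray(long_axis, dtype=float)
    long_axis = long_axis / np.linalg.norm(long_axis)
    vox = np.linalg.norm(np.asarray(affine)[:3, :3], axis=0)

    filled = np.where(np.isfinite(depth), depth, np.nan)
    fill = np.ones_like(filled)  # outside the wall: epicardial side
    if cavity is not None:
        fill[np.asarray(cavity, dtype=bool)] = 0.0
    filled = np.where(np.isnan(filled), fill, filled)
    if smooth_voxels > 0:
        filled = gaussian_filter(filled, sigma=smooth_voxels)

    gx, gy = np.gradient(filled, vox[0], vox[1], axis=(0, 1))
    grad = np.stack([gx, gy, np.zeros_like(gx)], axis=-1)
    gnorm = np.linalg.norm(grad, axis=-1)

    # degenerate: a genuine transmural gradient is ~1/thickness (1/mm); a
    # wall thicker than 20 mm is implausible, so anything below 0.05/mm is
    # a flat spot (e.g. smoothing leakage into a constant-depth region)
    valid = myocardium & (gnorm > 0.05)
    r_hat = np.zeros(grad.shape)
    r_hat[valid] = grad[valid] / gnorm[valid, None]

    l_raw = long_axis - (r_hat @ long_axis)[..., None] * r_hat
    l_norm = np.linalg.norm(l_raw, axis=-1)
    valid &= l_norm > 1e-6
    l_hat = np.zeros_like(l_raw)
    l_hat[valid] = l_raw[valid] / l_norm[valid, None]
    c_hat = np.cross(l_hat, r_hat)

    frames = np.stack([c_hat, l_hat, r_hat], axis=-2)
    return frames, valid


@dataclass
class LVGeometry:
    """The assembled anatomical scaffold of one left ventricle."""

    myocardium: np.ndarray
    cavity: np.ndarray
    depth: np.ndarray
    profiles: pd.DataFrame        # per-profile wall thickness
    layer_labels: np.ndarray      # LAYER_* codes
    region_labels: np.ndarray     # REGION_* codes
    segment_ids: np.ndarray       # AHA 1..17
    frames: np.ndarray            # (..., 3, 3), rows c, l, r
    frame_valid: np.ndarray
    affine: np.ndarray
    long_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def wall_thickness_by_region(self) -> pd.DataFrame:
        """Mean profile thickness per base/mid/apex region (and global)."""
        prof = self.profiles.copy()
        codes = self.region_labels[
            prof["i_endo"], prof["j_endo"], prof["slice"]
        ]
        prof["region"] = [REGION_NAMES.get(int(c), "none") for c in codes]
        rows = [
            {"region": "global",
             "thickness_mm": float(prof["thickness_mm"].mean()),
             "n_profiles": int(len(prof))}
        ]
        for region, sub in prof.groupby("region"):
            rows.append(
                {"region": region,
                 "thickness_mm": float(sub["thickness_mm"].mean()),
                 "n_profiles": int(len(sub))}
            )
        return pd.DataFrame(rows)


def build_geometry(
    myocardium: np.ndarray,
    cavity: np.ndarray,
    affine: np.ndarray,
    long_axis=None,
    reference_angle: float = 0.0,
    depth_method: str = "distance_ratio",
    smooth_voxels: float = 1.0,
) -> LVGeometry:
    """Run the full geometry stage from the two masks.

    ``long_axis`` defaults to the grid z-axis (the phantom convention); pass
    ``"auto"`` to use the principal axis of the wall mask.
    """
    if long_axis is None:
        long_axis = np.array([0.0, 0.0, 1.0])
    elif isinstance(long_axis, str):
        if long_axis != "auto":
            raise ValueError(f"unknown long_axis {long_axis!r}")
        long_axis = estimate_long_axis(myocardium)
    else:
        long_axis = np.asarray(long_axis, dtype=float)
        long_axis = long_axis / np.linalg.norm(long_axis)

    depth, profiles = build_profiles(
        myocardium, cavity, affine, depth_method=depth_method
    )
    layer_labels = split_layers(depth)
    region_labels, segment_ids = assign_regions(
        myocardium, cavity, long_axis=long_axis, reference_angle=reference_angle
    )
    frames, valid = local_frames(
        depth, myocardium, affine, long_axis=long_axis, cavity=cavity,
        smooth_voxels=smooth_voxels,
    )
    return LVGeometry(
        myocardium=np.asarray(myocardium, dtype=bool),
        cavity=np.asarray(cavity, dtype=bool),
        depth=depth,
        profiles=profiles,
        layer_labels=layer_labels,
        region_labels=region_labels,
        segment_ids=segment_ids,
        frames=frames,
        frame_valid=valid,
        affine=np.asarray(affine, dtype=float),
        long_axis=long_axis,
    )
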
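"""Reading and writing the standard diffusion-MRI formats.

The pipeline exchanges data as NIfTI-1 volumes plus FSL-style ``bval``/``bvec``
whitespace text files (one row of b-values; three rows of x/y/z gradient
components).  Gradient vectors are stored in the image voxel coordinate frame
(the FSL dialect); pass ``frame="scanner"`` to the readers/writers to treat
them as scanner-frame instead — the flag is recorded on the table so that
downstream code can tell which convention is in force.

Voxel indices are 0-based everywhere; physical (mm) coordinates are obtained
through the NIfTI affine only.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "GradientTable",
    "DWIVolume",
    "read_dwi",
    "write_dwi",
    "read_gradient_table",
    "write_gradient_table",
    "write_maps",
    "read_mask",
]

#: b-values at or below this (s/mm^2) count as unweighted reference frames.
B0_THRESHOLD = 10.0

#: acceptable deviation of a gradient-vector norm before re-normalisation.
_RENORM_WINDOW = (0.99, 1.01)
_UNIT_TOL = 1e-6


@dataclass(frozen=True)
class GradientTable:
    """Diffusion encoding: per-frame b-values and unit gradient directions.

    Parameters
    ----------
    bvals : (n,) array
        b-value of every 4D frame, s/mm^2.
    bvecs : (n, 3) array
        Gradient direction per frame.  Directions of weighted frames must be
        unit-norm within 1e-6; b=0 rows may be zero vectors.
    frame : {"voxel", "scanner"}
        Coordinate frame the vectors are expressed in.
    """

    bvals: np.ndarray
    bvecs: np.ndarray
    frame: str = "voxel"

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float).reshape(-1)
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise ValueError(f"bvecs must be (n, 3), got {bvecs.shape}")
        if len(bvals) != len(bvecs):
            raise ValueError(
                f"bvals has {len(bvals)} entries but bvecs has {len(bvecs)} rows"
            )
        if self.frame not in ("voxel", "scanner"):
            raise ValueError(f"unknown gradient frame {self.frame!r}")
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)
        b0 = bvals <= B0_THRESHOLD
        norms = np.linalg.norm(bvecs[~b0], axis=1)
        if norms.size and np.any(np.abs(norms - 1.0) > _UNIT_TOL):
            bad = int(np.argmax(np.abs(norms - 1.0)))
            raise ValueError(
                "non-unit gradient vector for a diffusion-weighted frame "
                f"(worst norm {norms[bad]:.6f}); renormalise or fix the bvec file"
            )
        if not np.any(b0):
            raise ValueError("gradient table has no b=0 reference frame")

    @property
    def b0_mask(self) -> np.ndarray:
        """Boolean mask of unweighted (b = 0) frames."""
        return self.bvals <= B0_THRESHOLD

    @property
    def n_frames(self) -> int:
        return len(self.bvals)

    @property
    def n_directions(self) -> int:
        """Number of diffusion-weighted frames."""
        return int(np.sum(~self.b0_mask))

    def design_rank(self) -> int:
        """Rank of the tensor design matrix built from the weighted frames."""
        g = self.bvecs[~self.b0_mask]
        if g.shape[0] == 0:
            return 0
        x = np.stack(
            [
                g[:, 0] ** 2,
                g[:, 1] ** 2,
                g[:, 2] ** 2,
                2 * g[:, 0] * g[:, 1],
                2 * g[:, 0] * g[:, 2],
                2 * g[:, 1] * g[:, 2],
            ],
            axis=1,
        )
        return int(np.linalg.matrix_rank(x, tol=1e-8))


@dataclass
class DWIVolume:
    """A 4D diffusion-weighted volume with its voxel→mm affine.

    Frame order along the 4th axis matches the associated
    :class:`GradientTable`.
    """

    data: np.ndarray
    affine: np.ndarray = field(
        default_factory=lambda: np.diag([0.1, 0.1, 0.1, 1.0])
    )

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"DWI data must be 4D, got {self.data.ndim}D")
        if any(s < 8 for s in self.data.shape[:3]):
            raise ValueError(
                f"spatial dimensions must be >= 8 voxels, got {self.data.shape[:3]}"
            )
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if np.any(self.data < 0):
            raise ValueError("DWI signal must be non-negative")

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm per spatial axis."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]


def read_gradient_table(bval_path, bvec_path, frame: str = "voxel") -> GradientTable:
    """Read FSL-style bval/bvec text files.

    Vector norms within [0.99, 1.01] are silently re-normalised (round-trip
    of low-precision text); anything further off is an error.
    """
    bvals = np.loadtxt(bval_path, dtype=float).reshape(-1)
    bvecs = np.loadtxt(bvec_path, dtype=float)
    if bvecs.ndim != 2 or 3 not in bvecs.shape:
        raise ValueError(f"bvec file {bvec_path} is not a 3-row/3-column table")
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        # ambiguous 3x3: FSL convention is 3 rows of n columns
        bvecs = bvecs.T
    if len(bvals) != len(bvecs):
        raise ValueError(
            f"bval file lists {len(bvals)} frames but bvec file lists "
            f"{len(bvecs)} directions"
        )
    weighted = bvals > B0_THRESHOLD
    norms = np.linalg.norm(bvecs[weighted], axis=1)
    lo, hi = _RENORM_WINDOW
    if norms.size:
        if np.any((norms < lo) | (norms > hi)):
            bad = int(np.argmax(np.abs(norms - 1.0)))
            raise ValueError(
                f"gradient vector norm {norms[bad]:.4f} outside [{lo}, {hi}]; "
                "refusing to renormalise"
            )
        bvecs = bvecs.copy()
        bvecs[weighted] /= norms[:, None]
    return GradientTable(bvals=bvals, bvecs=bvecs, frame=frame)


def write_gradient_table(gtab: GradientTable, bval_path, bvec_path) -> None:
    """Write FSL-style bval (one row) and bvec (three rows) text files."""
    np.savetxt(bval_path, gtab.bvals[None, :], fmt="%.6g")
    np.savetxt(bvec_path, gtab.bvecs.T, fmt="%.17g")


def read_dwi(nifti_path, bval_path, bvec_path, frame: str = "voxel"):
    """Read a 4D NIfTI plus its gradient files.

    Returns
    -------
    (DWIVolume, GradientTable)

    Raises
    ------
    ValueError
        If the image is not 4D or the frame count disagrees with the
        gradient table (the error names both counts).
    """
    img = nib.load(os.fspath(nifti_path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise ValueError(f"expected a 4D image, got {data.ndim}D from {nifti_path}")
    gtab = read_gradient_table(bval_path, bvec_path, frame=frame)
    if data.shape[3] != gtab.n_frames:
        raise ValueError(
            f"image has {data.shape[3]} frames but the gradient table lists "
            f"{gtab.n_frames}"
        )
    return DWIVolume(data=data, affine=img.affine), gtab


def write_dwi(dwi: DWIVolume, gtab: GradientTable, nifti_path, bval_path, bvec_path):
    """Write a DWIVolume and its gradient table to disk."""
    nib.save(nib.Nifti1Image(dwi.data, dwi.affine), os.fspath(nifti_path))
    write_gradient_table(gtab, bval_path, bvec_path)


#: value ranges enforced for known angle maps (degrees).
_MAP_RANGES = {
    "HA": (-90.0, 90.0),
    "absE2A": (0.0, 90.0),
}


def write_maps(maps, affine, out_dir, units=None, valid_ranges=None):
    """Write a set of scalar maps as one NIfTI each plus a TSV manifest.

    Parameters
    ----------
    maps : dict[str, ndarray]
        Map name → 3D array.  All maps must share a grid.
    affine : (4, 4) array
        Shared voxel→mm affine.
    out_dir : path
        Created if absent.
    units : dict[str, str], optional
        Unit string per map, recorded in the manifest.
    valid_ranges : dict[str, (lo, hi)], optional
        Extra range guards; NaN is always allowed (invalid voxels).
        Helix/sheetlet angle maps named ``HA``/``absE2A`` are guarded by
        default (±90° and [0°, 90°]).

    Returns
    -------
    dict[str, str]
        Map name → written file path.
    """
    units = units or {}
    ranges = dict(_MAP_RANGES)
    ranges.update(valid_ranges or {})
    os.makedirs(out_dir, exist_ok=True)
    shapes = {name: np.asarray(m).shape for name, m in maps.items()}
    if len(set(shapes.values())) > 1:
        raise ValueError(f"maps do not share a grid: {shapes}")
    written = {}
    lines = ["name\tfile\tunits"]
    for name, arr in maps.items():
        arr = np.asarray(arr, dtype=np.float64)
        if name in ranges:
            lo, hi = ranges[name]
            vals = arr[np.isfinite(arr)]
            if vals.size and (vals.min() < lo or vals.max() > hi):
                raise ValueError(
                    f"map {name!r} has values outside [{lo}, {hi}] "
                    f"(range {vals.min():.3f}..{vals.max():.3f})"
                )
        path = os.path.join(os.fspath(out_dir), f"{name}.nii.gz")
        nib.save(nib.Nifti1Image(arr, np.asarray(affine, dtype=float)), path)
        written[name] = path
        lines.append(f"{name}\t{os.path.basename(path)}\t{units.get(name, '')}")
    with open(os.path.join(os.fspath(out_dir), "maps_manifest.tsv"), "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return written


def read_mask(path) -> np.ndarray:
    """Read a NIfTI mask as boolean."""
    img = nib.load(os.fspath(path))
    return np.asarray(img.dataobj) > 0
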
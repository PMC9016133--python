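"""Voxelwise diffusion tensor estimation and scalar maps.

The estimator follows the modelling-object idiom: build a
:class:`DiffusionTensorModel` from a DWI volume and its gradient table, call
:meth:`~DiffusionTensorModel.fit`, and read estimates and diagnostics off the
returned :class:`TensorFitResult`.

The model is the monoexponential (Stejskal–Tanner) signal equation

    S_i = S0 * exp(-b_i g_i' D g_i)

solved per voxel by least squares on the log-attenuation.  S0 is the
arithmetic mean of the b=0 frames.  Negative eigenvalues are reported and
flagged, never clipped; eigenvector signs are arbitrary and all downstream
angle code is sign-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import DWIVolume, GradientTable
from .phantom import tensor6_to_matrix

__all__ = ["DiffusionTensorModel", "TensorFitResult", "fractional_anisotropy"]

#: floor applied to non-positive attenuations before the log, as a fraction of S0
_SIGNAL_FLOOR = 1e-6


def _design_matrix(gtab: GradientTable) -> np.ndarray:
    g = gtab.bvecs[~gtab.b0_mask]
    b = gtab.bvals[~gtab.b0_mask]
    return -b[:, None] * np.stack(
        [g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
         2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2], 2 * g[:, 1] * g[:, 2]],
        axis=1,
    )


def fractional_anisotropy(evals: np.ndarray) -> np.ndarray:
    """FA from eigenvalues: sqrt(3/2 * sum((l-MD)^2) / sum(l^2)).

    Defined as 0 for an all-zero tensor (not NaN).  Computed from raw
    eigenvalues even when some are negative, so QC can see the value.
    """
    evals = np.asarray(evals, dtype=float)
    md = evals.mean(axis=-1, keepdims=True)
    num = np.sum((evals - md) ** 2, axis=-1)
    den = np.sum(evals**2, axis=-1)
    out = np.zeros(num.shape)
    nz = den > 0
    out[nz] = np.sqrt(1.5 * num[nz] / den[nz])
    return out


class DiffusionTensorModel:
    """Log-linear least-squares diffusion tensor model.

    Parameters
    ----------
    dwi : DWIVolume
    gtab : GradientTable
        Must provide >= 6 non-collinear weighted directions (full design
        rank) and >= 1 b=0 frame.
    mask : bool array, optional
        Voxels to fit; default all.

    Raises
    ------
    ValueError
        All-b0 acquisitions, rank-deficient direction sets, or a mask that
        does not match the grid are rejected at construction.
    """

    def __init__(self, dwi: DWIVolume, gtab: GradientTable, mask=None):
        if dwi.n_frames != gtab.n_frames:
            raise ValueError(
                f"volume has {dwi.n_frames} frames, gradient table {gtab.n_frames}"
            )
        if gtab.n_directions == 0:
            raise ValueError("all frames are b=0: tensor model is undefined")
        if gtab.n_directions < 6:
            raise ValueError(
                f"{gtab.n_directions} weighted directions underdetermine the tensor"
            )
        rank = gtab.design_rank()
        if rank < 6:
            raise ValueError(
                f"gradient directions span a rank-{rank} design (need 6): "
                "directions are collinear/coplanar"
            )
        self.dwi = dwi
        self.gtab = gtab
        if mask is None:
            mask = np.ones(dwi.data.shape[:3], dtype=bool)
        mask = np.asarray(mask).astype(bool)
        if mask.shape != dwi.data.shape[:3]:
            raise ValueError("mask shape does not match the image grid")
        self.mask = mask
        self._X = _design_matrix(gtab)

    def fit(self, method: str = "ols") -> "TensorFitResult":
        """Fit the tensor in every masked voxel.

        method : {"ols", "wls"}
            Ordinary least squares on log-signal (default) or weighted LS
            with weights S_i^2 (first-order variance stabilisation).
        """
        if method not in ("ols", "wls"):
            raise ValueError(f"unknown method {method!r}")
        data = self.dwi.data
        mask = self.mask
        weighted = ~self.gtab.b0_mask
        s0 = data[..., self.gtab.b0_mask].mean(axis=-1)

        sig = data[mask][:, weighted]  # (n_vox, n_dirs)
        s0_m = s0[mask]
        floor = _SIGNAL_FLOOR * np.maximum(s0_m, np.finfo(float).tiny)[:, None]
        clipped = (sig <= 0) | (s0_m[:, None] <= 0)
        sig_safe = np.maximum(sig, floor)
        s0_safe = np.maximum(s0_m, np.finfo(float).tiny)
        y = np.log(sig_safe) - np.log(s0_safe)[:, None]

        X = self._X
        if method == "ols":
            pinv = np.linalg.pinv(X)
            d6 = y @ pinv.T
        else:
            # normal equations per voxel, weights S_i^2
            w = sig_safe**2
            Xw = X[None, :, :] * w[:, :, None]
            lhs = np.einsum("nfi,fj->nij", Xw, X)
            rhs = np.einsum("nfi,nf->ni", Xw, y)
            d6 = np.linalg.solve(lhs, rhs[..., None])[..., 0]

        tensors = np.zeros(data.shape[:3] + (6,))
        tensors[mask] = d6

        evals, evecs = np.linalg.eigh(tensor6_to_matrix(d6))
        order = np.argsort(evals, axis=-1)[..., ::-1]
        evals = np.take_along_axis(evals, order, axis=-1)
        evecs = np.take_along_axis(evecs, order[..., None, :], axis=-1)

        ev_field = np.zeros(data.shape[:3] + (3,))
        ev_field[mask] = evals
        evec_field = np.zeros(data.shape[:3] + (3, 3))
        evec_field[mask] = evecs

        neg = np.zeros(data.shape[:3], dtype=bool)
        neg[mask] = evals[..., 2] < 0
        clip_flag = np.zeros(data.shape[:3], dtype=bool)
        clip_flag[mask] = clipped.any(axis=1)

        return TensorFitResult(
            model=self,
            tensors=tensors,
            eigenvalues=ev_field,
            eigenvectors=evec_field,
            s0=s0 * mask,
            mask=mask,
            negative_eigenvalue=neg,
            clipped_signal=clip_flag,
            method=method,
        )


@dataclass
class TensorFitResult:
    """Per-voxel tensor estimates, eigensystem, scalar maps and QC flags.

    Eigenvectors are the columns of ``eigenvectors[..., :, k]`` for
    eigenvalue ``eigenvalues[..., k]`` (descending order, so k=0 is E1).
    """

    model: DiffusionTensorModel
    tensors: np.ndarray          # (..., 6)
    eigenvalues: np.ndarray      # (..., 3) descending
    eigenvectors: np.ndarray     # (..., 3, 3) columns
    s0: np.ndarray
    mask: np.ndarray
    negative_eigenvalue: np.ndarray
    clipped_signal: np.ndarray
    method: str = "ols"
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def primary_eigenvector(self) -> np.ndarray:
        return self.eigenvectors[..., :, 0]

    @property
    def secondary_eigenvector(self) -> np.ndarray:
        return self.eigenvectors[..., :, 1]

    @property
    def md(self) -> np.ndarray:
        """Mean diffusivity (l1+l2+l3)/3, mm^2/s."""
        return self.eigenvalues.mean(axis=-1)

    @property
    def fa(self) -> np.ndarray:
        if "fa" not in self._cache:
            fa = fractional_anisotropy(self.eigenvalues)
            fa[~self.mask] = 0.0
            self._cache["fa"] = fa
        return self._cache["fa"]

    def scalar_maps(self) -> dict:
        """Scalar maps keyed by conventional names (MD, FA, lambda1..3)."""
        return {
            "MD": self.md,
            "FA": self.fa,
            "lambda1": self.eigenvalues[..., 0],
            "lambda2": self.eigenvalues[..., 1],
            "lambda3": self.eigenvalues[..., 2],
        }

    def summary(self) -> str:
        """Plain-text summary of the fit over the mask."""
        m = self.mask
        nvox = int(m.sum())
        lines = [
            "Diffusion tensor fit",
            "====================",
            f"method:               {self.method}",
            f"voxels fitted:        {nvox}",
            f"weighted directions:  {self.model.gtab.n_directions}",
            f"b=0 frames:           {int(self.model.gtab.b0_mask.sum())}",
            f"b_max (s/mm^2):       {self.model.gtab.bvals.max():.6g}",
            f"negative eigenvalues: {int(self.negative_eigenvalue.sum())} voxels",
            f"clipped signals:      {int(self.clipped_signal.sum())} voxels",
        ]
        if nvox:
            md, fa = self.md[m], self.fa[m]
            lines += [
                f"MD  (mm^2/s): median {np.median(md):.4e}  IQR "
                f"[{np.percentile(md, 25):.4e}, {np.percentile(md, 75):.4e}]",
                f"FA:           median {np.median(fa):.4f}  IQR "
                f"[{np.percentile(fa, 25):.4f}, {np.percentile(fa, 75):.4f}]",
            ]
        return "\n".join(lines)
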
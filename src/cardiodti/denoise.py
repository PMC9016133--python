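"""Overcomplete local-PCA denoising of 4D diffusion-weighted stacks.

Each local patch (default 5x5x5 voxels across all frames) is decomposed by
principal component analysis; eigenvalues compatible with pure noise under a
Marchenko–Pastur (random-matrix) law are suppressed and the patch is
reconstructed from the remaining signal components.  Patches overlap (the
"overcomplete" aspect) and every voxel's estimates are averaged.

The noise level is estimated per patch from the discarded eigenvalue tail
("auto", the default) or fixed globally via ``sigma``.  The procedure
operates on magnitude data and applies no Rician bias correction;
``debias_hook`` accepts a callable applied to the denoised stack for users
who want one.

The result is deterministic: no randomness is involved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .io import DWIVolume

__all__ = ["DenoiseParams", "local_pca_denoise"]


@dataclass(frozen=True)
class DenoiseParams:
    """Parameters of the local-PCA stage.

    window_radius : int
        Patch half-width in voxels (2 → 5x5x5 patches).  The patch must
        hold more voxels than the stack has frames so the local PCA is
        overdetermined.
    sigma : float or "auto"
        Noise standard deviation; "auto" estimates it per patch from the
        Marchenko–Pastur tail.
    threshold_rule : str
        Eigenvalue cutoff rule; only "marchenko-pastur" is implemented.
    stride : int
        Spacing of patch corners; 1 gives the fully overcomplete transform,
        larger values trade accuracy for speed (edge patches are always
        included so every voxel is covered).
    """

    window_radius: int = 2
    sigma: float | str = "auto"
    threshold_rule: str = "marchenko-pastur"
    stride: int = 1

    def __post_init__(self) -> None:
        if self.window_radius < 1:
            raise ValueError("window_radius must be >= 1")
        if self.threshold_rule != "marchenko-pastur":
            raise ValueError(f"unknown threshold_rule {self.threshold_rule!r}")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if not (self.sigma == "auto" or (
            isinstance(self.sigma, (int, float)) and self.sigma >= 0
        )):
            raise ValueError("sigma must be 'auto' or a non-negative number")


def _corner_grid(extent: int, window: int, stride: int) -> np.ndarray:
    """Patch corner positions covering [0, extent) including the tail."""
    if extent < window:
        raise ValueError(f"window {window} does not fit in extent {extent}")
    xs = list(range(0, extent - window + 1, stride))
    if xs[-1] != extent - window:
        xs.append(extent - window)
    return np.asarray(xs)


def _signal_components(evals_asc: np.ndarray, n_vox: int, sigma) -> np.ndarray:
    """Boolean keep-mask per component from the MP eigenvalue cutoff.

    ``evals_asc``: (n_patches, F) ascending eigenvalues of the patch
    covariance C C'/N.  For "auto", the largest t is found such that the t
    smallest eigenvalues are consistent with an MP bulk of aspect t/N whose
    variance is their own mean; those t components are treated as noise.
    """
    n_patch, F = evals_asc.shape
    if sigma == "auto":
        t = np.arange(1, F + 1)
        cummean = np.cumsum(evals_asc, axis=1) / t
        edge = cummean * (1.0 + np.sqrt(t / n_vox)) ** 2
        consistent = evals_asc <= edge + 1e-30
        t_noise = (consistent * t).max(axis=1)
    else:
        thr = float(sigma) ** 2 * (1.0 + np.sqrt(F / n_vox)) ** 2
        t_noise = np.sum(evals_asc <= thr, axis=1)
    keep = np.arange(F)[None, :] >= t_noise[:, None]
    return keep


def local_pca_denoise(
    dwi: DWIVolume, params: DenoiseParams = DenoiseParams(), mask=None
) -> DWIVolume:
    """Denoise a 4D DWI volume by overcomplete local PCA.

    Parameters
    ----------
    dwi : DWIVolume
        At least 7 frames (fewer cannot separate a noise bulk).
    params : DenoiseParams
    mask : bool array, optional
        Restrict processing to the mask's bounding box (padded by one
        window); voxels outside the processed box pass through unchanged.

    Returns
    -------
    DWIVolume of the same shape and affine.
    """
    data = dwi.data.astype(np.float64)
    nx, ny, nz, F = data.shape
    if F < 7:
        raise ValueError(
            f"{F} frames are too few for spectral noise separation (need >= 7)"
        )
    w = 2 * params.window_radius + 1
    n_vox = w**3
    if n_vox <= F:
        raise ValueError(
            f"patch of {n_vox} voxels must exceed the {F} frames; "
            "increase window_radius"
        )

    lo = np.zeros(3, dtype=int)
    hi = np.array([nx, ny, nz])
    if mask is not None:
        idx = np.argwhere(np.asarray(mask, dtype=bool))
        if idx.size == 0:
            return DWIVolume(data=data.copy(), affine=dwi.affine.copy())
        lo = np.maximum(idx.min(axis=0) - w, 0)
        hi = np.minimum(idx.max(axis=0) + w + 1, hi)

    xs = _corner_grid(int(hi[0] - lo[0]), w, params.stride) + lo[0]
    ys = _corner_grid(int(hi[1] - lo[1]), w, params.stride) + lo[1]
    zs = _corner_grid(int(hi[2] - lo[2]), w, params.stride) + lo[2]

    acc = np.zeros_like(data)
    cnt = np.zeros(data.shape[:3])
    view = sliding_window_view(data, (w, w, w), axis=(0, 1, 2))
    # view shape: (nx-w+1, ny-w+1, nz-w+1, F, w, w, w)

    for z0 in zs:
        patches = view[np.ix_(xs, ys, [z0])][:, :, 0]  # (len(xs), len(ys), F, w, w, w)
        p = patches.reshape(len(xs) * len(ys), F, n_vox).copy()
        mean = p.mean(axis=2, keepdims=True)
        c = p - mean
        gram = np.einsum("pfi,pgi->pfg", c, c) / n_vox
        evals, evecs = np.linalg.eigh(gram)          # ascending
        keep = _signal_components(evals, n_vox, params.sigma)
        vk = evecs * keep[:, None, :]
        proj = np.einsum("pfk,pgk->pfg", vk, vk)     # rank-truncated projector
        dn = np.einsum("pfg,pgi->pfi", proj, c) + mean
        dn = dn.reshape(len(xs), len(ys), F, w, w, w)

        for dx in range(w):
            for dy in range(w):
                for dz in range(w):
                    acc[np.ix_(xs + dx, ys + dy, [z0 + dz])] += dn[
                        :, :, None, :, dx, dy, dz
                    ]
                    cnt[np.ix_(xs + dx, ys + dy, [z0 + dz])] += 1.0

    out = data.copy()
    touched = cnt > 0
    out[touched] = acc[touched] / cnt[touched, None]
    np.maximum(out, 0.0, out=out)  # magnitude data stays non-negative
    return DWIVolume(data=out, affine=dwi.affine.copy())
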
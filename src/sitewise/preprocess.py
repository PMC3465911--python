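"""Volume-level preprocessing: smoothing, downsampling, masking, flattening.

The pipeline for structural maps is smooth → downsample → group mask →
flatten; fMRI-derived maps (already at coarse resolution) skip the first two
steps.  All operations are deterministic and order-stable so that the same
inputs always give bit-identical feature vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "GroupMask",
    "smooth_volume",
    "downsample_half",
    "build_group_mask",
    "flatten_masked",
    "scatter_masked",
    "load_volume",
    "save_volume",
    "save_mask",
    "structural_vectors",
]

# FWHM = sigma * 2*sqrt(2*ln 2)
_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class GroupMask:
    """Boolean voxel-retention mask shared by a set of volumes."""

    mask: np.ndarray

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def shape(self):
        return self.mask.shape


def smooth_volume(volume: np.ndarray, diameter_voxels: float = 3.0) -> np.ndarray:
    """Gaussian-smooth a volume.

    ``diameter_voxels`` is interpreted as the kernel's full width at half
    maximum in voxel units (the standard neuroimaging smoothing parameter),
    so sigma = diameter / 2.3548.  Boundaries use reflect padding, which
    preserves total intensity up to truncation effects.
    """
    if diameter_voxels <= 0:
        raise ValueError("diameter_voxels must be positive")
    vol = np.asarray(volume, dtype=float)
    sigma = diameter_voxels * _FWHM_TO_SIGMA
    return ndimage.gaussian_filter(vol, sigma=sigma, mode="reflect")


def downsample_half(volume: np.ndarray) -> np.ndarray:
    """Halve each dimension by averaging 2×2×2 blocks.

    Output size along each axis is ceil(n/2); a trailing partial block is
    averaged over the voxels it actually contains.
    """
    vol = np.asarray(volume, dtype=float)
    if any(s < 2 for s in vol.shape):
        raise ValueError("each dimension must be at least 2")
    for axis in range(vol.ndim):
        n = vol.shape[axis]
        starts = np.arange(0, n, 2)
        sums = np.add.reduceat(vol, starts, axis=axis)
        counts = np.minimum(starts + 2, n) - starts
        shape = [1] * vol.ndim
        shape[axis] = len(starts)
        vol = sums / counts.reshape(shape)
    return vol


def build_group_mask(volumes, min_fraction: float = 0.05) -> GroupMask:
    """Retain voxels that are non-zero in at least ``min_fraction`` of volumes.

    The retention rule is inclusive at the boundary: with 20 volumes and a
    voxel non-zero in exactly one of them, the fraction 0.05 is retained at
    the default threshold.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    volumes = [np.asarray(v) for v in volumes]
    if not volumes:
        raise ValueError("need at least one volume")
    shape = volumes[0].shape
    if any(v.shape != shape for v in volumes):
        raise ValueError("all volumes must share one shape")
    nonzero = np.zeros(shape, dtype=int)
    for v in volumes:
        nonzero += v != 0
    frac = nonzero / len(volumes)
    return GroupMask(mask=frac >= min_fraction)


def flatten_masked(volume: np.ndarray, mask: GroupMask) -> np.ndarray:
    """Flatten the retained voxels into a vector in row-major scan order."""
    vol = np.asarray(volume, dtype=float)
    if vol.shape != mask.shape:
        raise ValueError(f"shape mismatch: {vol.shape} vs mask {mask.shape}")
    return vol[mask.mask]


def scatter_masked(vector: np.ndarray, mask: GroupMask) -> np.ndarray:
    """Inverse of :func:`flatten_masked`; non-retained voxels are zero."""
    vec = np.asarray(vector, dtype=float)
    if vec.size != mask.n_voxels:
        raise ValueError("vector length does not match retained-voxel count")
    out = np.zeros(mask.shape, dtype=float)
    out[mask.mask] = vec
    return out


def load_volume(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata(), dtype=float)


def save_volume(volume: np.ndarray, path, affine=None) -> None:
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float64), affine), str(path))


def save_mask(mask: GroupMask, path, affine=None) -> None:
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(mask.mask.astype(np.uint8), affine), str(path))


def structural_vectors(volumes, diameter_voxels: float = 3.0, min_fraction: float = 0.05):
    """smooth → downsample → group-mask → flatten, for a set of volumes.

    Returns ``(matrix, mask)`` where matrix rows follow the input order.
    """
    processed = [downsample_half(smooth_volume(v, diameter_voxels)) for v in volumes]
    mask = build_group_mask(processed, min_fraction=min_fraction)
    return np.vstack([flatten_masked(v, mask) for v in processed]), mask
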
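"""Intensity and geometry preprocessing for chest CT.

Implements the fixed preprocessing chain used throughout the package:
resampling to an isotropic-in-plane grid, truncation of Hounsfield units to
[-1000, 1000] with scaling to (-1, 1), the automatic body-contour mask used
before slice-wise feature extraction, and the byte normalization that maps
CT numbers onto the [0, 255] range expected by RGB convolutional backbones.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .volume import HU, NORMALIZED, CTVolume

__all__ = [
    "resample_volume",
    "clip_scale_hu",
    "inverse_scale",
    "body_mask",
    "vgg_byte_normalize",
    "HU_CLIP",
    "BODY_THRESHOLD_HU",
]

# Truncation window applied before normalization.
HU_CLIP = (-1000.0, 1000.0)
# Body-contour threshold: everything denser than this is candidate body.
BODY_THRESHOLD_HU = -500.0


def resample_volume(vol: CTVolume, target_spacing: tuple[float, float, float]) -> CTVolume:
    """Resample ``vol`` to ``target_spacing`` (x, y, z) mm, linearly per axis.

    The output grid shape is ``round(shape * spacing / target_spacing)`` per
    axis; sample points are voxel indices scaled by the spacing ratio, so an
    intensity field that is affine in the voxel coordinates is reproduced
    exactly away from the clamped boundary.
    """
    target_spacing = tuple(float(s) for s in target_spacing)
    if len(target_spacing) != 3 or any(s <= 0 for s in target_spacing):
        raise ValueError(f"target spacing must be three positive numbers, got {target_spacing}")
    if vol.values.ndim != 3:
        raise ValueError("resample_volume expects a 3D volume")
    if any(n < 2 for n in vol.values.shape):
        raise ValueError("volume must have at least 2 voxels per axis")

    # array axes (z, y, x) vs spacing (x, y, z)
    old = np.array(vol.spacing[::-1], dtype=float)
    new = np.array(target_spacing[::-1], dtype=float)
    shape = np.asarray(vol.values.shape)
    new_shape = np.maximum(np.round(shape * old / new).astype(int), 1)

    ratio = new / old  # index step in old-grid units
    grids = np.meshgrid(
        *[np.arange(n, dtype=float) * r for n, r in zip(new_shape, ratio)],
        indexing="ij",
    )
    out = ndimage.map_coordinates(
        np.asarray(vol.values, dtype=float), np.stack(grids), order=1, mode="nearest"
    )
    return CTVolume(out, spacing=target_spacing, units=vol.units, subject_id=vol.subject_id)


def clip_scale_hu(vol: CTVolume) -> CTVolume:
    """Truncate HU values to [-1000, 1000] and scale to (-1, 1) by /1000."""
    if vol.units != HU:
        raise ValueError("clip_scale_hu expects a volume in Hounsfield units")
    lo, hi = HU_CLIP
    out = np.clip(np.asarray(vol.values, dtype=float), lo, hi) / 1000.0
    return vol.with_values(out, units=NORMALIZED)


def inverse_scale(vol: CTVolume) -> CTVolume:
    """Map a normalized volume back to Hounsfield units (multiply by 1000)."""
    if vol.units != NORMALIZED:
        raise ValueError("inverse_scale expects a normalized volume")
    return vol.with_values(np.asarray(vol.values, dtype=float) * 1000.0, units=HU)


def body_mask(vol: CTVolume, threshold_hu: float = BODY_THRESHOLD_HU) -> np.ndarray:
    """Automatic body-contour mask.

    Thresholds at ``HU > threshold_hu``, applies a morphological opening with
    a 5x5 square structuring element per axial slice, then fills interior
    holes slice-wise.  Works on a 2D slice or a 3D volume; returns a boolean
    grid of the same shape.
    """
    if vol.units != HU:
        raise ValueError("body_mask expects a volume in Hounsfield units")
    values = np.asarray(vol.values)
    squeeze = values.ndim == 2
    if squeeze:
        values = values[None]

    mask = values > threshold_hu
    selem = np.ones((1, 5, 5), dtype=bool)
    mask = ndimage.binary_opening(mask, structure=selem)
    filled = np.empty_like(mask)
    for z in range(mask.shape[0]):
        filled[z] = ndimage.binary_fill_holes(mask[z])
    return filled[0] if squeeze else filled


def vgg_byte_normalize(vol: CTVolume) -> np.ndarray:
    """Map CT numbers to byte intensities replicated over 3 channels.

    ``y = floor(255 * (x + 1000) / 2000)``, then clipped to [0, 255]; the
    result is returned as ``uint8`` with a trailing channel axis of size 3.
    """
    if vol.units != HU:
        raise ValueError("vgg_byte_normalize expects a volume in Hounsfield units")
    x = np.asarray(vol.values, dtype=float)
    y = np.floor(255.0 * (x + 1000.0) / 2000.0)
    y = np.clip(y, 0, 255).astype(np.uint8)
    return np.repeat(y[..., None], 3, axis=-1)
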
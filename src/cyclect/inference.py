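"""Whole-volume synthesis by center-weighted sliding-window prediction.

The trained generator only sees cubic patches, so volumes are translated
window by window on a stride grid (last window per axis clamped to the
boundary for full coverage).  Overlapping predictions are blended with a
separable tent weight that favors each patch's center, where the generator
has the most context, over its borders.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import NORMALIZED, CTVolume

__all__ = ["WeightKernel", "make_weight_kernel", "sliding_window_translate", "difference_map", "DifferenceMap"]

WEIGHT_FLOOR = 0.05


@dataclass(frozen=True)
class WeightKernel:
    """Patch-shaped positive blending weights, maximal at the center."""

    values: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.values <= 0):
            raise ValueError("blending weights must be strictly positive")


def make_weight_kernel(size: int, floor: float = WEIGHT_FLOOR) -> WeightKernel:
    """Separable tent kernel ``w(i,j,k) = t(i) t(j) t(k)``.

    ``t`` rises linearly from ``floor`` at the patch border to 1 at the
    center; for an even size the two central planes tie at the maximum.
    The floor keeps border voxels covered by a single window well-defined.
    """
    if size < 2:
        raise ValueError("kernel size must be >= 2")
    c = (size - 1) / 2.0
    i = np.arange(size, dtype=np.float64)
    t = floor + (1.0 - floor) * (1.0 - np.abs(i - c) / c)
    w = t[:, None, None] * t[None, :, None] * t[None, None, :]
    return WeightKernel(w)


def _window_starts(dim: int, patch: int, stride: int) -> list[int]:
    starts = list(range(0, dim - patch + 1, stride))
    if starts[-1] != dim - patch:
        starts.append(dim - patch)
    return starts


def sliding_window_translate(
    vol,
    generator,
    patch_size: int = 64,
    stride: int = 16,
) -> CTVolume | np.ndarray:
    """Translate a whole normalized volume through ``generator``.

    Every output voxel is the weight-normalized average of all patch
    predictions covering it; accumulation uses double precision so the
    result is independent of window visiting order.
    """
    is_vol = isinstance(vol, CTVolume)
    values = np.asarray(vol.values if is_vol else vol, dtype=np.float32)
    if is_vol and vol.units != NORMALIZED:
        raise ValueError("sliding_window_translate expects a normalized volume")
    if values.ndim != 3:
        raise ValueError("expected a 3D volume")
    if any(n < patch_size for n in values.shape):
        raise ValueError(
            f"volume shape {values.shape} smaller than patch size {patch_size}; "
            "pad the volume before synthesis"
        )
    if not 1 <= stride <= patch_size:
        raise ValueError("stride must satisfy 1 <= stride <= patch_size")

    weight = make_weight_kernel(patch_size).values
    acc = np.zeros(values.shape, dtype=np.float64)
    wsum = np.zeros(values.shape, dtype=np.float64)
    for z0 in _window_starts(values.shape[0], patch_size, stride):
        for y0 in _window_starts(values.shape[1], patch_size, stride):
            for x0 in _window_starts(values.shape[2], patch_size, stride):
                sl = (
                    slice(z0, z0 + patch_size),
                    slice(y0, y0 + patch_size),
                    slice(x0, x0 + patch_size),
                )
                pred = np.asarray(generator(values[sl]), dtype=np.float64)
                acc[sl] += weight * pred
                wsum[sl] += weight
    out = (acc / wsum).astype(np.float64)
    if is_vol:
        return vol.with_values(np.clip(out, -1.0, 1.0), units=NORMALIZED)
    return out


@dataclass(frozen=True)
class DifferenceMap:
    """Clipped intensity difference with its rendering range."""

    values: np.ndarray
    vmin: float
    vmax: float


def difference_map(a, b, clip: float = 0.4) -> DifferenceMap:
    """Difference ``a - b`` on the normalized scale, clipped to ±``clip``."""
    av = np.asarray(a.values if isinstance(a, CTVolume) else a, dtype=np.float64)
    bv = np.asarray(b.values if isinstance(b, CTVolume) else b, dtype=np.float64)
    if av.shape != bv.shape:
        raise ValueError(f"shape mismatch: {av.shape} vs {bv.shape}")
    return DifferenceMap(np.clip(av - bv, -clip, clip), -clip, clip)
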
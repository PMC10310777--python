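"""Volumetric CT container.

Voxel grids are indexed ``(z, y, x)`` (axial slices first), 0-based, while
``spacing`` is stored ``(x, y, z)`` in millimetres following the NIfTI
convention.  Intensities are either calibrated Hounsfield units (``"HU"``)
or the GAN-facing normalized scale in ``[-1, 1]`` (``"normalized"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

HU = "HU"
NORMALIZED = "normalized"

__all__ = ["CTVolume", "HU", "NORMALIZED"]


@dataclass
class CTVolume:
    """A scalar intensity grid with voxel spacing metadata.

    Parameters
    ----------
    values
        2D or 3D array of intensities, indexed ``(z, y, x)`` (or ``(y, x)``
        for a single axial slice).
    spacing
        Voxel spacing ``(x, y, z)`` in mm; strictly positive.
    units
        ``"HU"`` for Hounsfield units, ``"normalized"`` for values in
        ``[-1, 1]``.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    units: str = HU
    subject_id: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim not in (2, 3):
            raise ValueError(f"expected a 2D or 3D grid, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive numbers, got {self.spacing}")
        if self.units not in (HU, NORMALIZED):
            raise ValueError(f"units must be {HU!r} or {NORMALIZED!r}, got {self.units!r}")
        if self.units == NORMALIZED:
            lo, hi = float(np.min(self.values)), float(np.max(self.values))
            if lo < -1.0 - 1e-6 or hi > 1.0 + 1e-6:
                raise ValueError(
                    f"normalized volume has values outside [-1, 1] (range {lo:.3g}..{hi:.3g})"
                )

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    def with_values(self, values: np.ndarray, units: str | None = None) -> "CTVolume":
        """Return a copy carrying new voxel values (same spacing/id)."""
        return CTVolume(
            values=values,
            spacing=self.spacing,
            units=self.units if units is None else units,
            subject_id=self.subject_id,
        )
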
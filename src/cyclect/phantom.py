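"""Procedural thorax phantoms for unpaired contrast / non-contrast cohorts.

The generator emits pairs of 3D volumes that are voxelwise identical except
for a localized hyperintensity (``contrast_delta_hu``) on tubular
vessel-like structures, mimicking the way iodinated contrast brightens
vascular and cardiac structures on chest CT while leaving lung parenchyma
and soft tissue unchanged.  Released cohorts expose only one domain per
subject (the unpaired training regime); a hidden registry keeps the paired
counterpart and the body/lung/vessel masks for evaluation.

Geometry is deliberately simple: an ellipsoidal body in air, two ellipsoidal
lungs, and ``n_vessels`` polyline tubes of fixed radius threaded through the
chest.  Per-subject geometric jitter (axis scales and offsets) plus
independent Gaussian acquisition noise provide the between-subject
variability a discriminator could otherwise latch onto.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .volume import HU, CTVolume

__all__ = ["PhantomConfig", "PhantomPair", "generate_phantom_pair", "generate_cohorts", "save_cohorts"]

AIR_HU = -1000.0
_MIN_GRID = 16  # smallest grid that can hold body + lungs + a tube


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions for the synthetic cohorts.

    HU means sit inside the [-1000, 1000] truncation window used by the
    preprocessing chain; the default contrast boost of +300 HU is typical of
    arterial-phase enhancement in great vessels.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)  # (z, y, x) voxels
    spacing: tuple[float, float, float] = (1.0, 1.0, 2.0)  # (x, y, z) mm
    body_hu: float = 40.0
    lung_hu: float = -800.0
    vessel_hu: float = 60.0
    contrast_delta_hu: float = 300.0
    noise_sd_hu: float = 20.0
    n_vessels: int = 4
    vessel_radius: tuple[int, int] = (2, 4)  # inclusive voxel range
    geometry_jitter: float = 0.08  # relative scale/offset range per subject
    seed: int = 0

    def validate(self) -> None:
        if len(self.grid_shape) != 3 or any(int(n) < _MIN_GRID for n in self.grid_shape):
            raise ValueError(
                f"grid_shape {self.grid_shape} too small for the requested geometry "
                f"(need >= {_MIN_GRID} voxels per axis)"
            )
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        for name in ("body_hu", "lung_hu", "vessel_hu"):
            v = getattr(self, name)
            if not -1000.0 <= v <= 1000.0:
                raise ValueError(f"{name}={v} outside [-1000, 1000] HU")
        if self.contrast_delta_hu < 0:
            raise ValueError("contrast_delta_hu must be >= 0")
        if self.noise_sd_hu < 0:
            raise ValueError("noise_sd_hu must be >= 0")
        if self.n_vessels < 0:
            raise ValueError("n_vessels must be >= 0")
        if self.geometry_jitter < 0:
            raise ValueError("geometry_jitter must be >= 0")
        rlo, rhi = self.vessel_radius
        if not (1 <= rlo <= rhi):
            raise ValueError("vessel_radius must satisfy 1 <= lo <= hi")


@dataclass
class PhantomPair:
    """Hidden ground truth: paired volumes plus region masks."""

    contrast: CTVolume
    noncontrast: CTVolume
    body_mask: np.ndarray
    lung_mask: np.ndarray
    vessel_mask: np.ndarray
    subject_id: str


def _ellipsoid(shape: tuple[int, int, int], center: np.ndarray, semi: np.ndarray) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    acc = np.zeros(shape, dtype=float)
    for g, c, a in zip(grids, center, semi):
        acc += ((g - c) / a) ** 2
    return acc <= 1.0


def _rasterize_tube(mask: np.ndarray, waypoints: np.ndarray, radius: int) -> None:
    """Mark spheres of ``radius`` along the polyline in-place."""
    shape = np.asarray(mask.shape)
    offs = np.arange(-radius, radius + 1)
    ball = (
        offs[:, None, None] ** 2 + offs[None, :, None] ** 2 + offs[None, None, :] ** 2
    ) <= radius**2
    for p0, p1 in zip(waypoints[:-1], waypoints[1:]):
        seg = p1 - p0
        n_steps = max(int(np.ceil(np.linalg.norm(seg) / 0.5)), 1)
        for t in np.linspace(0.0, 1.0, n_steps + 1):
            c = np.round(p0 + t * seg).astype(int)
            lo = np.maximum(c - radius, 0)
            hi = np.minimum(c + radius + 1, shape)
            if np.any(lo >= hi):
                continue
            blo = lo - (c - radius)
            bhi = blo + (hi - lo)
            mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= ball[
                blo[0]:bhi[0], blo[1]:bhi[1], blo[2]:bhi[2]
            ]


def _build_geometry(cfg: PhantomConfig, rng: np.random.Generator):
    shape = tuple(int(n) for n in cfg.grid_shape)
    dims = np.asarray(shape, dtype=float)  # (z, y, x)
    j = cfg.geometry_jitter
    scale = rng.uniform(1.0 - j, 1.0 + j, size=3) if j > 0 else np.ones(3)
    offset = rng.uniform(-j, j, size=3) * dims / 4.0 if j > 0 else np.zeros(3)

    center = dims / 2.0 + offset
    body_semi = np.array([0.46, 0.36, 0.42]) * dims * scale  # (z, y, x)
    body = _ellipsoid(shape, center, body_semi)

    lung_semi = np.array([0.32, 0.22, 0.15]) * dims * scale
    lungs = np.zeros(shape, dtype=bool)
    for side in (-1.0, 1.0):
        c = center + np.array([0.0, 0.0, side * 0.21 * dims[2] * scale[2]])
        lungs |= _ellipsoid(shape, c, lung_semi)
    lungs &= body

    vessels = np.zeros(shape, dtype=bool)
    rlo, rhi = cfg.vessel_radius
    # waypoint box: central chest region, comfortably inside the body
    lo_box = center - np.array([0.36, 0.24, 0.26]) * dims * scale
    hi_box = center + np.array([0.36, 0.24, 0.26]) * dims * scale
    lo_box = np.maximum(lo_box, 1)
    hi_box = np.minimum(hi_box, dims - 2)
    for _ in range(cfg.n_vessels):
        n_way = int(rng.integers(3, 6))
        pts = rng.uniform(lo_box, hi_box, size=(n_way, 3))
        pts = pts[np.argsort(pts[:, 0])]  # run roughly head-foot
        radius = int(rng.integers(rlo, rhi + 1))
        _rasterize_tube(vessels, pts, radius)
    from scipy import ndimage

    interior = ndimage.binary_erosion(body, iterations=2)
    vessels &= interior
    return body, lungs, vessels


def generate_phantom_pair(cfg: PhantomConfig, seed: int) -> PhantomPair:
    """Generate one paired contrast / non-contrast phantom.

    Deterministic for fixed ``(cfg, seed)``.  The two volumes are voxelwise
    identical outside the vessel mask (up to independent acquisition noise);
    inside it the contrast volume is brighter by ``contrast_delta_hu``.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence((int(cfg.seed), int(seed))))
    body, lungs, vessels = _build_geometry(cfg, rng)

    base = np.full(cfg.grid_shape, AIR_HU, dtype=np.float64)
    base[body] = cfg.body_hu
    base[lungs] = cfg.lung_hu
    base[vessels] = cfg.vessel_hu

    contrast = base.copy()
    contrast[vessels] += cfg.contrast_delta_hu
    noncontrast = base

    if cfg.noise_sd_hu > 0:
        contrast = contrast + rng.normal(0.0, cfg.noise_sd_hu, size=contrast.shape)
        noncontrast = noncontrast + rng.normal(0.0, cfg.noise_sd_hu, size=noncontrast.shape)
    contrast = np.clip(contrast, -1000.0, 1000.0)
    noncontrast = np.clip(noncontrast, -1000.0, 1000.0)

    sid = f"S{int(seed):04d}"
    return PhantomPair(
        contrast=CTVolume(contrast, spacing=cfg.spacing, units=HU, subject_id=sid),
        noncontrast=CTVolume(noncontrast, spacing=cfg.spacing, units=HU, subject_id=sid),
        body_mask=body,
        lung_mask=lungs,
        vessel_mask=vessels,
        subject_id=sid,
    )


def generate_cohorts(
    cfg: PhantomConfig,
    n_contrast: int,
    n_noncontrast: int,
    seed: int = 0,
) -> tuple[list[CTVolume], list[CTVolume], dict[str, PhantomPair]]:
    """Generate two unpaired cohorts plus the hidden pair registry.

    Each subject gets an independent geometry draw; the released cohorts
    expose a single domain per subject, while the registry retains the
    hidden counterpart and masks for evaluation only.
    """
    cfg.validate()
    if n_contrast < 1 or n_noncontrast < 1:
        raise ValueError("cohort sizes must be >= 1")
    registry: dict[str, PhantomPair] = {}
    contrast_cohort: list[CTVolume] = []
    noncontrast_cohort: list[CTVolume] = []
    for i in range(n_contrast + n_noncontrast):
        pair = generate_phantom_pair(cfg, seed=int(seed) * 100_000 + i)
        registry[pair.subject_id] = pair
        if i < n_contrast:
            contrast_cohort.append(pair.contrast)
        else:
            noncontrast_cohort.append(pair.noncontrast)
    return contrast_cohort, noncontrast_cohort, registry


def save_cohorts(
    contrast: list[CTVolume],
    noncontrast: list[CTVolume],
    out_dir: str | Path,
    registry: dict[str, PhantomPair] | None = None,
) -> Path:
    """Write cohorts (and optionally masks) as NIfTI plus a TSV manifest."""
    from .io import write_volume

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.tsv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["subject_id", "domain", "path"])
        for domain, cohort in (("contrast", contrast), ("noncontrast", noncontrast)):
            for vol in cohort:
                if vol.subject_id is None:
                    warnings.warn("volume without subject_id; skipping manifest row")
                path = out_dir / f"{vol.subject_id}_{domain}.nii"
                write_volume(vol, path)
                writer.writerow([vol.subject_id, domain, path.name])
    if registry is not None:
        mask_dir = out_dir / "masks"
        mask_dir.mkdir(exist_ok=True)
        for sid, pair in registry.items():
            for name, mask in (
                ("body", pair.body_mask),
                ("lung", pair.lung_mask),
                ("vessel", pair.vessel_mask),
            ):
                write_volume(
                    CTVolume(mask.astype(np.uint8), spacing=pair.contrast.spacing, units=HU),
                    mask_dir / f"{sid}_{name}.nii",
                )
    return manifest


def unpaired_preset(**overrides) -> PhantomConfig:
    """The default study conditions used by tests and the demo pipeline."""
    return replace(PhantomConfig(), **overrides)
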
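"""Cycle-GAN model definitions and loss terms.

Two generators map normalized CT patches between the contrast (A) and
non-contrast (B) domains; two patch-GAN discriminators emit grids of local
realism scores.  The generator is a residual encoder/decoder: one
reflection-padded encoding convolution, two stride-2 down blocks, a stack
of residual units, two stride-2 transposed-convolution up blocks and a
final Tanh.  All normalization is per-instance.

Loss terms:

* adversarial — least-squares form, ``mean((D(fake) - 1)^2)`` for the
  generator and ``0.5 * [mean((D(real) - 1)^2) + mean(D(fake)^2)]`` for the
  discriminator;
* cycle consistency — the average of the L1 reconstruction error and the
  SSIM loss ``1 - SSIM``;
* identity — mean absolute change when a generator is fed a patch already
  in its output domain, weighted by ``lambda_identity`` (default 10).
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy import ndimage

from . import nn

F32 = np.float32

__all__ = [
    "GeneratorSpec",
    "DiscriminatorSpec",
    "LossWeights",
    "Generator",
    "Discriminator",
    "build_generator",
    "build_discriminator",
    "ssim",
    "cycle_consistency_loss",
    "identity_loss",
    "adversarial_generator_loss",
    "adversarial_discriminator_loss",
    "total_generator_loss",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """Architecture of the residual translation generator.

    The full-scale preset uses 64 base filters, nine residual units and a
    7-voxel encoding kernel; the tiny preset shrinks filters, depth and the
    encode/decode kernels so CPU experiments run in minutes.
    """

    base_filters: int = 64
    n_residual: int = 9
    encode_kernel: int = 7
    down_kernel: int = 3
    res_kernel: int = 3
    up_kernel: int = 3
    final_kernel: int = 7

    def validate(self) -> None:
        if self.base_filters < 1 or self.n_residual < 1:
            raise ValueError("base_filters and n_residual must be >= 1")
        for k in (self.encode_kernel, self.res_kernel, self.final_kernel):
            if k % 2 != 1:
                raise ValueError("encode/res/final kernels must be odd")

    @classmethod
    def full_scale(cls) -> "GeneratorSpec":
        return cls()

    @classmethod
    def tiny(cls) -> "GeneratorSpec":
        return cls(base_filters=8, n_residual=2, encode_kernel=3, final_kernel=3)


@dataclass(frozen=True)
class DiscriminatorSpec:
    """Architecture of the patch-GAN discriminator (three stride-2 blocks)."""

    base_filters: int = 64
    n_down: int = 3
    down_kernel: int = 4
    final_kernel: int = 3

    def validate(self) -> None:
        if self.base_filters < 1 or self.n_down < 1:
            raise ValueError("base_filters and n_down must be >= 1")

    @classmethod
    def full_scale(cls) -> "DiscriminatorSpec":
        return cls()

    @classmethod
    def tiny(cls) -> "DiscriminatorSpec":
        return cls(base_filters=8)


@dataclass(frozen=True)
class LossWeights:
    """Scalar weights of the combined generator objective."""

    lambda_identity: float = 10.0

    def validate(self) -> None:
        if self.lambda_identity < 0:
            raise ValueError("lambda_identity must be >= 0")


class _Model:
    """Shared plumbing: parameter access and tape-based forward/backward."""

    net: nn.Sequential
    spec: GeneratorSpec | DiscriminatorSpec

    def parameters(self) -> list[nn.Parameter]:
        return self.net.parameters()

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("checkpoint parameter count mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"checkpoint shape mismatch: {p.data.shape} vs {a.shape}")
            p.data[...] = a


class Generator(_Model):
    """Patch-to-patch translator; callable on a ``(D, H, W)`` array."""

    def __init__(self, spec: GeneratorSpec, rng: np.random.Generator | None = None) -> None:
        spec.validate()
        rng = rng or np.random.default_rng()
        f = spec.base_filters
        ek, dk, rk, uk, fk = (
            spec.encode_kernel,
            spec.down_kernel,
            spec.res_kernel,
            spec.up_kernel,
            spec.final_kernel,
        )
        layers: list[nn.Layer] = [
            nn.ReflectionPad3d(ek // 2),
            nn.Conv3d(1, f, ek, rng=rng),
            nn.InstanceNorm3d(),
            nn.ReLU(),
            nn.Conv3d(f, 2 * f, dk, stride=2, pad=dk // 2, rng=rng),
            nn.InstanceNorm3d(),
            nn.ReLU(),
            nn.Conv3d(2 * f, 4 * f, dk, stride=2, pad=dk // 2, rng=rng),
            nn.InstanceNorm3d(),
            nn.ReLU(),
        ]
        for _ in range(spec.n_residual):
            layers.append(
                nn.Residual(
                    nn.Sequential(
                        nn.ReflectionPad3d(rk // 2),
                        nn.Conv3d(4 * f, 4 * f, rk, rng=rng),
                        nn.InstanceNorm3d(),
                        nn.ReLU(),
                        nn.ReflectionPad3d(rk // 2),
                        nn.Conv3d(4 * f, 4 * f, rk, rng=rng),
                        nn.InstanceNorm3d(),
                    )
                )
            )
        layers += [
            nn.ConvTranspose3d(4 * f, 2 * f, uk, stride=2, pad=uk // 2, opad=1, rng=rng),
            nn.InstanceNorm3d(),
            nn.ReLU(),
            nn.ConvTranspose3d(2 * f, f, uk, stride=2, pad=uk // 2, opad=1, rng=rng),
            nn.InstanceNorm3d(),
            nn.ReLU(),
            nn.ReflectionPad3d(fk // 2),
            nn.Conv3d(f, 1, fk, rng=rng),
            nn.Tanh(),
        ]
        self.spec = spec
        self.net = nn.Sequential(*layers)

    @staticmethod
    def _check_patch(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=F32)
        if x.ndim != 3:
            raise ValueError(f"generator expects a 3D patch, got shape {x.shape}")
        if any(n % 4 != 0 or n < 4 for n in x.shape):
            raise ValueError(
                f"patch sides must be positive multiples of 4 (two stride-2 stages), got {x.shape}"
            )
        return x

    def forward(self, x: np.ndarray):
        x = self._check_patch(x)
        y, tape = self.net.forward(x[None])
        return y[0], tape

    def backward(self, dy: np.ndarray, tape, need_input_grad: bool = True):
        dx = self.net.backward(np.asarray(dy, dtype=F32)[None], tape, need_input_grad)
        return None if dx is None else dx[0]

    def __call__(self, x: np.ndarray) -> np.ndarray:
        y, _ = self.forward(x)
        return y


class Discriminator(_Model):
    """Patch-GAN critic: maps a patch to a grid of scores in (0, 1)."""

    def __init__(self, spec: DiscriminatorSpec, rng: np.random.Generator | None = None) -> None:
        spec.validate()
        rng = rng or np.random.default_rng()
        f = spec.base_filters
        layers: list[nn.Layer] = []
        c_in = 1
        for i in range(spec.n_down):
            layers += [
                nn.Conv3d(c_in, f * 2**i, spec.down_kernel, stride=2, pad=1, rng=rng),
                nn.InstanceNorm3d(),
                nn.LeakyReLU(0.2),
            ]
            c_in = f * 2**i
        layers += [
            nn.Conv3d(c_in, 1, spec.final_kernel, stride=1, pad=spec.final_kernel // 2, rng=rng),
            nn.Sigmoid(),
        ]
        self.spec = spec
        self.net = nn.Sequential(*layers)

    def forward(self, x: np.ndarray):
        x = np.asarray(x, dtype=F32)
        if x.ndim != 3:
            raise ValueError(f"discriminator expects a 3D patch, got shape {x.shape}")
        if any(n < 2**self.spec.n_down for n in x.shape):
            raise ValueError(
                f"patch {x.shape} smaller than 2^{self.spec.n_down} per axis"
            )
        y, tape = self.net.forward(x[None])
        return y[0], tape

    def backward(self, dy: np.ndarray, tape, need_input_grad: bool = True):
        dx = self.net.backward(np.asarray(dy, dtype=F32)[None], tape, need_input_grad)
        return None if dx is None else dx[0]

    def __call__(self, x: np.ndarray) -> np.ndarray:
        y, _ = self.forward(x)
        return y


def build_generator(spec: GeneratorSpec, rng: np.random.Generator | None = None) -> Generator:
    return Generator(spec, rng)


def build_discriminator(spec: DiscriminatorSpec, rng: np.random.Generator | None = None) -> Discriminator:
    return Discriminator(spec, rng)


# ---------------------------------------------------------------------------
# SSIM with a Gaussian window
# ---------------------------------------------------------------------------

SSIM_WINDOW = 7
SSIM_SIGMA = 1.5
SSIM_L = 2.0  # dynamic range of normalized patches, [-1, 1]
SSIM_K1 = 0.01
SSIM_K2 = 0.03


def _gauss_kernel(win: int, sigma: float) -> np.ndarray:
    r = win // 2
    t = np.arange(-r, r + 1, dtype=np.float64)
    g = np.exp(-(t**2) / (2 * sigma**2))
    return g / g.sum()


def _filt_full(x: np.ndarray, g: np.ndarray) -> np.ndarray:
    for ax in range(3):
        x = ndimage.correlate1d(x, g, axis=ax, mode="constant")
    return x


def _filt_valid(x: np.ndarray, g: np.ndarray) -> np.ndarray:
    r = len(g) // 2
    y = _filt_full(x, g)
    return y[r:-r, r:-r, r:-r]


def _filt_adjoint(m: np.ndarray, g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    r = len(g) // 2
    z = np.zeros(shape, dtype=np.float64)
    z[r:-r, r:-r, r:-r] = m
    return _filt_full(z, g)


def _ssim_maps(x: np.ndarray, y: np.ndarray, g: np.ndarray):
    mx = _filt_valid(x, g)
    my = _filt_valid(y, g)
    sxx = _filt_valid(x * x, g) - mx * mx
    syy = _filt_valid(y * y, g) - my * my
    sxy = _filt_valid(x * y, g) - mx * my
    c1 = (SSIM_K1 * SSIM_L) ** 2
    c2 = (SSIM_K2 * SSIM_L) ** 2
    a1 = 2 * mx * my + c1
    a2 = 2 * sxy + c2
    b1 = mx * mx + my * my + c1
    b2 = sxx + syy + c2
    return mx, my, a1, a2, b1, b2


def ssim(a: np.ndarray, b: np.ndarray) -> float:
    """Mean local SSIM over 3D Gaussian-windowed neighborhoods.

    Uses a 7-voxel window with sigma 1.5 and dynamic range ``L = 2``
    (normalized patches).  The local maps are evaluated on the valid
    interior (no boundary padding) and averaged.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if a.ndim != 3 or any(n < SSIM_WINDOW for n in a.shape):
        raise ValueError(f"ssim needs a 3D patch with sides >= {SSIM_WINDOW}")
    g = _gauss_kernel(SSIM_WINDOW, SSIM_SIGMA)
    _, _, a1, a2, b1, b2 = _ssim_maps(a, b, g)
    return float(np.mean(a1 * a2 / (b1 * b2)))


def ssim_and_grad(x: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """SSIM value and its gradient with respect to the second argument."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    g = _gauss_kernel(SSIM_WINDOW, SSIM_SIGMA)
    mx, my, a1, a2, b1, b2 = _ssim_maps(x, y, g)
    n = a1.size
    s = a1 * a2 / (b1 * b2)
    value = float(s.mean())

    d_sxy = 2 * a1 / (b1 * b2)
    d_syy = -a1 * a2 / (b1 * b2 * b2)
    d_my = 2 * mx * a2 / (b1 * b2) - 2 * my * s / b1
    # chain through the filtered aggregates fy, f(y^2), f(xy)
    d_fy = d_my - 2 * my * d_syy - mx * d_sxy
    grad = (
        _filt_adjoint(d_fy, g, x.shape)
        + 2 * y * _filt_adjoint(d_syy, g, x.shape)
        + x * _filt_adjoint(d_sxy, g, x.shape)
    ) / n
    return value, grad


# ---------------------------------------------------------------------------
# Loss terms
# ---------------------------------------------------------------------------


def cycle_consistency_loss(x: np.ndarray, x_reconstructed: np.ndarray) -> float:
    """Average of the L1 error and the SSIM loss between input and cycle."""
    x = np.asarray(x, dtype=np.float64)
    xr = np.asarray(x_reconstructed, dtype=np.float64)
    if x.shape != xr.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {xr.shape}")
    l1 = float(np.mean(np.abs(x - xr)))
    return (l1 + (1.0 - ssim(x, xr))) / 2.0


def cycle_loss_and_grad(x: np.ndarray, xr: np.ndarray) -> tuple[float, np.ndarray]:
    """Cycle loss plus its gradient with respect to the reconstruction."""
    x = np.asarray(x, dtype=np.float64)
    xr = np.asarray(xr, dtype=np.float64)
    l1 = float(np.mean(np.abs(x - xr)))
    s, ds = ssim_and_grad(x, xr)
    grad = (np.sign(xr - x) / x.size - ds) / 2.0
    return (l1 + (1.0 - s)) / 2.0, grad.astype(F32)


def identity_loss(g, x: np.ndarray) -> float:
    """Mean absolute change when ``g`` is fed a same-domain patch."""
    y = g(x) if callable(g) else g
    return float(np.mean(np.abs(np.asarray(y, dtype=np.float64) - np.asarray(x, dtype=np.float64))))


def adversarial_generator_loss(d_scores: np.ndarray) -> float:
    """Least-squares generator term: ``mean((D(fake) - 1)^2)``."""
    d = np.asarray(d_scores, dtype=np.float64)
    return float(np.mean((d - 1.0) ** 2))


def adversarial_discriminator_loss(real_scores: np.ndarray, fake_scores: np.ndarray) -> float:
    """Least-squares discriminator term for real-vs-synthetic patches."""
    r = np.asarray(real_scores, dtype=np.float64)
    f = np.asarray(fake_scores, dtype=np.float64)
    return 0.5 * (float(np.mean((r - 1.0) ** 2)) + float(np.mean(f**2)))


def total_generator_loss(adv: float, cyc: float, idn: float, w: LossWeights) -> float:
    """Combined objective: adversarial + cycle + lambda * identity."""
    w.validate()
    return float(adv) + float(cyc) + w.lambda_identity * float(idn)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

_SPEC_CLASSES = {"generator": GeneratorSpec, "discriminator": DiscriminatorSpec}


def save_checkpoint(path, models: dict, meta: dict | None = None) -> None:
    """Serialize named models (weights + specs) into a single ``.npz`` file."""
    arrays: dict[str, np.ndarray] = {}
    descriptor: dict[str, dict] = {"models": {}, "meta": meta or {}}
    for name, model in models.items():
        kind = "generator" if isinstance(model, Generator) else "discriminator"
        descriptor["models"][name] = {"kind": kind, "spec": asdict(model.spec)}
        for i, arr in enumerate(model.state_arrays()):
            arrays[f"{name}/{i}"] = arr
    arrays["__descriptor__"] = np.frombuffer(
        json.dumps(descriptor).encode("utf-8"), dtype=np.uint8
    )
    with io.BytesIO() as buf:
        np.savez(buf, **arrays)
        data = buf.getvalue()
    with open(path, "wb") as fh:
        fh.write(data)


def load_checkpoint(path) -> tuple[dict, dict]:
    """Rebuild models from a checkpoint; returns ``(models, meta)``."""
    with np.load(path) as z:
        descriptor = json.loads(bytes(z["__descriptor__"]).decode("utf-8"))
        models: dict[str, _Model] = {}
        for name, info in descriptor["models"].items():
            spec = _SPEC_CLASSES[info["kind"]](**info["spec"])
            model = Generator(spec) if info["kind"] == "generator" else Discriminator(spec)
            n = len(model.parameters())
            model.load_state_arrays([z[f"{name}/{i}"] for i in range(n)])
            models[name] = model
    return models, descriptor["meta"]
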
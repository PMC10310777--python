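"""Stochastic unpaired patch training for the two generator/discriminator pairs.

Each iteration draws one random cubic patch per domain, takes one joint
Adam step on both generators (adversarial + cycle + weighted identity), and
one Adam step per discriminator against a history pool of previously
generated patches.  All randomness (weight init, patch positions, pool
swaps) flows from a single seeded stream so runs are bit-reproducible on
fixed hardware.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import gan
from .gan import DiscriminatorSpec, GeneratorSpec, LossWeights
from .volume import NORMALIZED, CTVolume

F32 = np.float32

__all__ = ["TrainConfig", "TrainHistory", "sample_patch", "ImagePool", "train_cyclegan"]

_HISTORY_KEYS = (
    "adv_ab",
    "adv_ba",
    "cycle_a",
    "cycle_b",
    "identity_a",
    "identity_b",
    "disc_a",
    "disc_b",
)


@dataclass
class TrainConfig:
    """Training hyperparameters.

    The full-scale preset trains 64-voxel patches with batch size 1 and
    Adam at learning rate 2e-4 for ~450,000 iterations; desk-scale runs
    shrink the patch, the model and the iteration count.
    """

    patch_size: int = 64
    batch_size: int = 1
    learning_rate: float = 2e-4
    beta1: float = 0.5
    beta2: float = 0.999
    n_iterations: int = 1000
    seed: int = 0
    checkpoint_every: int = 0  # 0 disables periodic checkpoints
    image_pool_size: int = 50  # 0 disables the history pool
    reject_air_patches: bool = False  # resample patches that are entirely air
    air_threshold: float = -0.95  # normalized scale

    def validate(self) -> None:
        if self.patch_size % 4 != 0 or self.patch_size < 8:
            raise ValueError("patch_size must be a multiple of 4 and >= 8")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.batch_size != 1:
            raise ValueError("only batch_size = 1 is supported")


@dataclass
class TrainHistory:
    """Per-iteration loss components for both directions."""

    records: dict[str, list[float]] = field(
        default_factory=lambda: {k: [] for k in _HISTORY_KEYS}
    )

    def append(self, iteration: int, **values: float) -> None:
        for key, v in values.items():
            if not np.isfinite(v):
                raise FloatingPointError(
                    f"non-finite loss term {key!r} = {v} at iteration {iteration}"
                )
            self.records[key].append(float(v))

    def __len__(self) -> int:
        return len(next(iter(self.records.values())))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.records)


def _as_values(vol) -> np.ndarray:
    if isinstance(vol, CTVolume):
        if vol.units != NORMALIZED:
            raise ValueError("training volumes must be normalized (run clip_scale_hu first)")
        return np.asarray(vol.values, dtype=F32)
    return np.asarray(vol, dtype=F32)


def sample_patch(vol, size: int, rng: np.random.Generator) -> np.ndarray:
    """Draw a cubic sub-grid with its corner uniform over valid positions."""
    values = _as_values(vol)
    if values.ndim != 3:
        raise ValueError("sample_patch expects a 3D volume")
    if any(n < size for n in values.shape):
        raise ValueError(
            f"volume shape {values.shape} smaller than requested patch size {size}"
        )
    corner = [int(rng.integers(0, n - size + 1)) for n in values.shape]
    z, y, x = corner
    return values[z : z + size, y : y + size, x : x + size]


class ImagePool:
    """History buffer of generated patches for discriminator updates.

    With probability 1/2 a query returns a stored patch (replacing it with
    the new one); otherwise the fresh patch passes through.  Size 0 disables
    the buffer.
    """

    def __init__(self, size: int, rng: np.random.Generator) -> None:
        self.size = size
        self.rng = rng
        self.items: list[np.ndarray] = []

    def query(self, patch: np.ndarray) -> np.ndarray:
        if self.size <= 0:
            return patch
        if len(self.items) < self.size:
            self.items.append(patch.copy())
            return patch
        if self.rng.random() < 0.5:
            idx = int(self.rng.integers(0, self.size))
            out = self.items[idx]
            self.items[idx] = patch.copy()
            return out
        return patch


def _sample_training_patch(cohort, cfg: TrainConfig, rng: np.random.Generator) -> np.ndarray:
    for _ in range(20):
        vol = cohort[int(rng.integers(0, len(cohort)))]
        patch = sample_patch(vol, cfg.patch_size, rng)
        if not cfg.reject_air_patches or float(patch.max()) > cfg.air_threshold:
            return patch
    return patch


def train_cyclegan(
    cohort_a,
    cohort_b,
    gen_spec: GeneratorSpec | None = None,
    disc_spec: DiscriminatorSpec | None = None,
    weights: LossWeights | None = None,
    cfg: TrainConfig | None = None,
    out_dir: str | Path | None = None,
):
    """Train ``G_AB``, ``G_BA``, ``D_A``, ``D_B`` on two unpaired cohorts.

    Returns ``(g_ab, g_ba, d_a, d_b, history)``.  Cohorts are sequences of
    normalized volumes (``CTVolume`` or arrays).  A non-finite loss aborts
    with a diagnostic naming the offending term and iteration.
    """
    gen_spec = gen_spec or GeneratorSpec()
    disc_spec = disc_spec or DiscriminatorSpec()
    weights = weights or LossWeights()
    cfg = cfg or TrainConfig()
    cfg.validate()
    weights.validate()
    if len(cohort_a) == 0 or len(cohort_b) == 0:
        raise ValueError("both cohorts must be non-empty")
    cohort_a = [_as_values(v) for v in cohort_a]
    cohort_b = [_as_values(v) for v in cohort_b]

    rng = np.random.default_rng(cfg.seed)
    g_ab = gan.Generator(gen_spec, rng)
    g_ba = gan.Generator(gen_spec, rng)
    d_a = gan.Discriminator(disc_spec, rng)
    d_b = gan.Discriminator(disc_spec, rng)

    opt_g = gan.nn.Adam(
        g_ab.parameters() + g_ba.parameters(), cfg.learning_rate, cfg.beta1, cfg.beta2
    )
    opt_da = gan.nn.Adam(d_a.parameters(), cfg.learning_rate, cfg.beta1, cfg.beta2)
    opt_db = gan.nn.Adam(d_b.parameters(), cfg.learning_rate, cfg.beta1, cfg.beta2)
    pool_a = ImagePool(cfg.image_pool_size, rng)
    pool_b = ImagePool(cfg.image_pool_size, rng)

    history = TrainHistory()
    lam = weights.lambda_identity

    for it in range(cfg.n_iterations):
        a = _sample_training_patch(cohort_a, cfg, rng)
        b = _sample_training_patch(cohort_b, cfg, rng)

        # ---- generator update (joint, both directions) ----
        fake_b, tape_fb = g_ab.forward(a)
        rec_a, tape_ra = g_ba.forward(fake_b)
        fake_a, tape_fa = g_ba.forward(b)
        rec_b, tape_rb = g_ab.forward(fake_a)
        idt_a, tape_ia = g_ba.forward(a)  # G_BA should leave domain-A patches alone
        idt_b, tape_ib = g_ab.forward(b)

        s_fb, dtape_fb = d_b.forward(fake_b)
        s_fa, dtape_fa = d_a.forward(fake_a)

        adv_ab = gan.adversarial_generator_loss(s_fb)
        adv_ba = gan.adversarial_generator_loss(s_fa)
        cyc_a, dcyc_a = gan.cycle_loss_and_grad(a, rec_a)
        cyc_b, dcyc_b = gan.cycle_loss_and_grad(b, rec_b)
        idn_a = float(np.mean(np.abs(idt_a - a)))
        idn_b = float(np.mean(np.abs(idt_b - b)))

        opt_g.zero_grad()
        # adversarial branches (discriminator grads discarded before D step)
        d_b.zero_grad()
        d_a.zero_grad()
        dfake_b = d_b.backward((2.0 / s_fb.size) * (s_fb - 1.0), dtape_fb)
        dfake_a = d_a.backward((2.0 / s_fa.size) * (s_fa - 1.0), dtape_fa)
        # cycle branches
        dfake_b = dfake_b + g_ba.backward(dcyc_a, tape_ra)
        dfake_a = dfake_a + g_ab.backward(dcyc_b, tape_rb)
        g_ab.backward(dfake_b, tape_fb, need_input_grad=False)
        g_ba.backward(dfake_a, tape_fa, need_input_grad=False)
        # identity branches
        g_ba.backward(lam * np.sign(idt_a - a) / idt_a.size, tape_ia, need_input_grad=False)
        g_ab.backward(lam * np.sign(idt_b - b) / idt_b.size, tape_ib, need_input_grad=False)
        opt_g.step()

        # ---- discriminator updates ----
        hist_fa = pool_a.query(fake_a)
        hist_fb = pool_b.query(fake_b)

        d_a.zero_grad()
        s_real_a, t_ra = d_a.forward(a)
        s_hfa, t_hfa = d_a.forward(hist_fa)
        loss_da = gan.adversarial_discriminator_loss(s_real_a, s_hfa)
        d_a.backward((1.0 / s_real_a.size) * (s_real_a - 1.0), t_ra, need_input_grad=False)
        d_a.backward((1.0 / s_hfa.size) * s_hfa, t_hfa, need_input_grad=False)
        opt_da.step()

        d_b.zero_grad()
        s_real_b, t_rb = d_b.forward(b)
        s_hfb, t_hfb = d_b.forward(hist_fb)
        loss_db = gan.adversarial_discriminator_loss(s_real_b, s_hfb)
        d_b.backward((1.0 / s_real_b.size) * (s_real_b - 1.0), t_rb, need_input_grad=False)
        d_b.backward((1.0 / s_hfb.size) * s_hfb, t_hfb, need_input_grad=False)
        opt_db.step()

        history.append(
            it,
            adv_ab=adv_ab,
            adv_ba=adv_ba,
            cycle_a=cyc_a,
            cycle_b=cyc_b,
            identity_a=idn_a,
            identity_b=idn_b,
            disc_a=loss_da,
            disc_b=loss_db,
        )

        if out_dir is not None and cfg.checkpoint_every > 0 and (it + 1) % cfg.checkpoint_every == 0:
            out_dir = Path(out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            gan.save_checkpoint(
                out_dir / f"checkpoint_{it + 1:07d}.npz",
                {"g_ab": g_ab, "g_ba": g_ba, "d_a": d_a, "d_b": d_b},
                meta={"iteration": it + 1, "seed": cfg.seed},
            )

    return g_ab, g_ba, d_a, d_b, history
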
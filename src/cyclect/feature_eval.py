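"""Pooled deep-feature binary classification harness.

A frozen convolutional backbone maps each body-masked, byte-normalized CT
slice to a fixed-length vector by taking, per output channel, the maximum
over all spatial positions.  A small fully connected head (sigmoid hidden
units, He-uniform initialization, L1 weight/bias penalty, sigmoid output)
is then trained with binary cross entropy to separate two slice cohorts.
Repeating the fit with resampled validation subsets yields mean ± standard
error learning curves, and a shuffled-label control provides the
random-choice null against which real separability is judged.

The default backbone is a small random-weight convolutional stack: features
from random projections are untrained but still separate cohorts whose
intensity statistics differ, which is all the harness itself requires.  An
adapter for a pretrained VGG16 (512 channels) can be plugged in through the
same ``FeatureExtractor`` contract where such weights are available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Protocol

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.metrics import roc_auc_score

from .preprocess import body_mask, vgg_byte_normalize
from .volume import HU, CTVolume

F32 = np.float32

__all__ = [
    "FeatureExtractor",
    "TinyConvBackbone",
    "extract_pooled_features",
    "ClassifierHeadSpec",
    "TrainSchedule",
    "CurveStats",
    "train_head",
    "shuffled_label_control",
]


class FeatureExtractor(Protocol):
    """Maps a 3-channel byte image to a fixed-length feature vector."""

    n_features: int

    def __call__(self, image: np.ndarray) -> np.ndarray: ...


class TinyConvBackbone:
    """Random-weight 2D convolutional stack with global max pooling.

    Deterministic for a fixed seed.  Channels grow ``3 -> width -> n_features``
    over two 3x3 convolution + ReLU stages.
    """

    def __init__(self, n_features: int = 8, width: int = 8, seed: int = 0) -> None:
        rng = np.random.default_rng(seed)
        self.n_features = n_features
        self.w1 = rng.normal(0, 0.5, size=(width, 3, 3, 3)).astype(F32)
        self.b1 = rng.normal(0, 0.1, size=width).astype(F32)
        self.w2 = rng.normal(0, 0.5, size=(n_features, width, 3, 3)).astype(F32)
        self.b2 = rng.normal(0, 0.1, size=n_features).astype(F32)

    @staticmethod
    def _conv(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
        out = np.empty((w.shape[0],) + x.shape[1:], dtype=F32)
        for o in range(w.shape[0]):
            acc = np.zeros(x.shape[1:], dtype=np.float64)
            for c in range(x.shape[0]):
                acc += ndimage.correlate(x[c].astype(np.float64), w[o, c], mode="constant")
            out[o] = acc + b[o]
        return out

    def __call__(self, image: np.ndarray) -> np.ndarray:
        if image.ndim != 3 or image.shape[-1] != 3:
            raise ValueError(f"expected an (H, W, 3) byte image, got {image.shape}")
        x = (np.asarray(image, dtype=F32) / 255.0).transpose(2, 0, 1)
        h = np.maximum(self._conv(x, self.w1, self.b1), 0.0)
        h = np.maximum(self._conv(h, self.w2, self.b2), 0.0)
        return h.reshape(self.n_features, -1).max(axis=1)


def extract_pooled_features(
    slices: list[CTVolume],
    extractor: FeatureExtractor,
    mask_fn: Callable[[CTVolume], np.ndarray] | None = body_mask,
) -> pd.DataFrame:
    """One feature row per axial HU slice.

    Each slice is body-masked (background air zeroed so features represent
    in-body regions only), byte-normalized, replicated to 3 channels and
    passed through the backbone; channel maxima form the row.
    """
    rows = []
    shape = None
    for i, sl in enumerate(slices):
        if sl.units != HU:
            raise ValueError("feature extraction expects HU slices")
        values = np.asarray(sl.values)
        if values.ndim != 2:
            raise ValueError("feature extraction expects 2D axial slices")
        if shape is None:
            shape = values.shape
        elif values.shape != shape:
            raise ValueError(f"inconsistent slice shapes: {values.shape} vs {shape}")
        byte = vgg_byte_normalize(sl)
        if mask_fn is not None:
            mask = mask_fn(sl)
            byte = byte * mask[..., None]
        rows.append(extractor(byte))
    index = [s.subject_id or f"slice{i:04d}" for i, s in enumerate(slices)]
    cols = [f"feat_{j:03d}" for j in range(extractor.n_features)]
    return pd.DataFrame(np.asarray(rows, dtype=float), index=index, columns=cols)


@dataclass(frozen=True)
class ClassifierHeadSpec:
    """Fully connected head: sigmoid hidden layers with L1 regularization."""

    hidden_sizes: tuple[int, ...] = (256, 128, 64, 32, 16)
    l1_penalty: float = 1e-5

    def validate(self) -> None:
        if any(b >= a for a, b in zip(self.hidden_sizes, self.hidden_sizes[1:])):
            raise ValueError("hidden sizes must be strictly decreasing")
        if self.l1_penalty < 0:
            raise ValueError("l1_penalty must be >= 0")


@dataclass(frozen=True)
class TrainSchedule:
    """Optimization schedule for the classifier head."""

    epochs: int = 2500
    learning_rate: float = 1e-4
    batch_size: int = 28
    n_validation: int = 48  # resampled per repeat, balanced between classes


@dataclass
class CurveStats:
    """Per-epoch mean and standard error over repeats, per split."""

    epochs: int
    repeats: int
    mean: dict[str, np.ndarray] = field(default_factory=dict)  # "<split>_<metric>"
    sem: dict[str, np.ndarray] = field(default_factory=dict)

    def final(self, key: str) -> tuple[float, float]:
        return float(self.mean[key][-1]), float(self.sem[key][-1])

    def to_frame(self) -> pd.DataFrame:
        data = {f"mean_{k}": v for k, v in self.mean.items()}
        data.update({f"sem_{k}": v for k, v in self.sem.items()})
        return pd.DataFrame(data)


class _MLPHead:
    """Sigmoid MLP with He-uniform init, trained by Adam on BCE + L1."""

    def __init__(self, n_in: int, spec: ClassifierHeadSpec, rng: np.random.Generator) -> None:
        sizes = [n_in, *spec.hidden_sizes, 1]
        self.weights, self.biases = [], []
        for a, b in zip(sizes[:-1], sizes[1:]):
            limit = np.sqrt(6.0 / a)
            self.weights.append(rng.uniform(-limit, limit, size=(a, b)))
            self.biases.append(rng.uniform(-limit, limit, size=b))
        self.l1 = spec.l1_penalty
        self.m = [np.zeros_like(w) for w in self.weights + self.biases]
        self.v = [np.zeros_like(w) for w in self.weights + self.biases]
        self.t = 0

    @staticmethod
    def _sigmoid(z: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        acts = [x]
        h = x
        for w, b in zip(self.weights, self.biases):
            h = self._sigmoid(h @ w + b)
            acts.append(h)
        return h[:, 0], acts

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)[0]

    def step(self, x: np.ndarray, y: np.ndarray, lr: float) -> float:
        p, acts = self.forward(x)
        eps = 1e-12
        bce = -np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
        delta = ((p - y) / len(y))[:, None]  # dBCE/dz for sigmoid output
        grads_w, grads_b = [], []
        for i in range(len(self.weights) - 1, -1, -1):
            gw = acts[i].T @ delta + self.l1 * np.sign(self.weights[i])
            gb = delta.sum(axis=0) + self.l1 * np.sign(self.biases[i])
            grads_w.append(gw)
            grads_b.append(gb)
            if i > 0:
                delta = (delta @ self.weights[i].T) * acts[i] * (1 - acts[i])
        grads = list(reversed(grads_w)) + list(reversed(grads_b))
        params = self.weights + self.biases
        self.t += 1
        b1, b2, eps_a = 0.9, 0.999, 1e-8
        for p_, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p_ -= lr * (m / (1 - b1**self.t)) / (np.sqrt(v / (1 - b2**self.t)) + eps_a)
        penalty = self.l1 * sum(np.abs(p_).sum() for p_ in params)
        return float(bce + penalty)


def _metrics(p: np.ndarray, y: np.ndarray) -> dict[str, float]:
    eps = 1e-12
    loss = float(-np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
    auc = float(roc_auc_score(y, p)) if len(np.unique(y)) == 2 else np.nan
    pred = p >= 0.5
    tp = float(np.sum(pred & (y == 1)))
    precision = tp / max(float(pred.sum()), 1.0)
    recall = tp / max(float((y == 1).sum()), 1.0)
    return {"loss": loss, "auc": auc, "precision": precision, "recall": recall}


def train_head(
    features: pd.DataFrame,
    labels: np.ndarray,
    spec: ClassifierHeadSpec | None = None,
    schedule: TrainSchedule | None = None,
    repeats: int = 30,
    seed: int = 0,
) -> CurveStats:
    """Train the head ``repeats`` times with resampled validation subsets.

    Each repeat draws a balanced validation set of ``schedule.n_validation``
    subjects, trains on the remainder, and records loss/AUC/precision/recall
    per epoch for both splits; curves are aggregated to mean ± SEM.
    """
    spec = spec or ClassifierHeadSpec()
    schedule = schedule or TrainSchedule()
    spec.validate()
    x_all = np.asarray(features, dtype=float)
    y_all = np.asarray(labels, dtype=float).ravel()
    classes = np.unique(y_all)
    if len(classes) < 2:
        raise ValueError("need both classes present to train the classifier")
    if schedule.n_validation >= len(y_all) or schedule.n_validation < 2:
        raise ValueError("n_validation must be in [2, n_subjects)")
    # standardize inputs on the pooled table (fit-time convenience)
    mu, sd = x_all.mean(axis=0), x_all.std(axis=0)
    x_all = (x_all - mu) / np.where(sd > 0, sd, 1.0)

    rng = np.random.default_rng(seed)
    per_repeat: dict[str, list[np.ndarray]] = {}
    half = schedule.n_validation // 2
    for _ in range(repeats):
        val_idx = np.concatenate(
            [rng.choice(np.flatnonzero(y_all == c), size=half, replace=False) for c in classes[:2]]
        )
        mask = np.zeros(len(y_all), dtype=bool)
        mask[val_idx] = True
        x_tr, y_tr = x_all[~mask], y_all[~mask]
        x_va, y_va = x_all[mask], y_all[mask]
        head = _MLPHead(x_all.shape[1], spec, rng)
        curves: dict[str, list[float]] = {}
        for _epoch in range(schedule.epochs):
            order = rng.permutation(len(y_tr))
            for start in range(0, len(order), schedule.batch_size):
                idx = order[start : start + schedule.batch_size]
                head.step(x_tr[idx], y_tr[idx], schedule.learning_rate)
            for split, (xs, ys) in (("train", (x_tr, y_tr)), ("val", (x_va, y_va))):
                for k, v in _metrics(head.predict(xs), ys).items():
                    curves.setdefault(f"{split}_{k}", []).append(v)
        for k, v in curves.items():
            per_repeat.setdefault(k, []).append(np.asarray(v))

    stats = CurveStats(epochs=schedule.epochs, repeats=repeats)
    for k, arrs in per_repeat.items():
        stacked = np.stack(arrs)
        stats.mean[k] = stacked.mean(axis=0)
        stats.sem[k] = stacked.std(axis=0, ddof=1) / np.sqrt(repeats) if repeats > 1 else np.zeros(
            stacked.shape[1]
        )
    return stats


def shuffled_label_control(labels: np.ndarray, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Uniform random permutation of the labels (class counts preserved)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = np.asarray(labels)
    return labels[rng.permutation(len(labels))]
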
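"""Sparse deep autoencoder compressing deep thermomics to a 16-d latent code.

Architecture: 8 dense layers — encoder 2048 -> 1024 -> 256 -> 64 -> 16 and
a mirrored, untied decoder — ReLU on every hidden layer (including the
bottleneck) and a sigmoid output. Training minimizes mean binary
cross-entropy between the min-max-scaled input features and the sigmoid
reconstruction, plus an l1 activity penalty (weight ``l1_weight``) on the
first encoder layer's activations, which drives a sparse distributed
representation. Optimized with Adam under a fixed seed; everything runs
in NumPy (float32), so training is reproducible run-to-run.

The default bottleneck of 16 on a 2048-d input is a 128x compression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = [
    "AutoencoderSpec",
    "TrainConfig",
    "MinMaxScaler",
    "LatentThermomics",
    "SparseAutoencoder",
    "bce_loss",
    "scale_features",
    "train_autoencoder",
    "encode",
]

_EPS = 1e-7


@dataclass
class AutoencoderSpec:
    """Layer schedule and regularization of the autoencoder."""

    dims: tuple[int, ...] = (2048, 1024, 256, 64, 16)
    l1_weight: float = 1e-5
    seed: int = 0
    tied: bool = False

    def __post_init__(self) -> None:
        d = tuple(int(x) for x in self.dims)
        if len(d) < 2 or any(d[i] <= d[i + 1] for i in range(len(d) - 1)):
            raise ValidationError("encoder dims must be strictly decreasing")
        self.dims = d

    @property
    def input_dim(self) -> int:
        return self.dims[0]

    @property
    def bottleneck(self) -> int:
        return self.dims[-1]

    @property
    def compression_factor(self) -> float:
        return self.dims[0] / self.dims[-1]


@dataclass
class TrainConfig:
    batch_size: int = 128
    epochs: int = 500
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    validation_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs < 1:
            raise ValidationError("batch_size and epochs must be >= 1")


@dataclass
class MinMaxScaler:
    """Per-feature min-max map to [0, 1]; constant features map to 0."""

    minimum: np.ndarray
    maximum: np.ndarray

    @property
    def constant_mask(self) -> np.ndarray:
        return self.maximum <= self.minimum

    def transform(self, X: np.ndarray) -> np.ndarray:
        span = np.where(self.constant_mask, 1.0, self.maximum - self.minimum)
        out = (np.asarray(X, dtype=np.float64) - self.minimum) / span
        out[:, self.constant_mask] = 0.0
        return out

    def inverse_transform(self, X01: np.ndarray) -> np.ndarray:
        span = np.where(self.constant_mask, 0.0, self.maximum - self.minimum)
        return np.asarray(X01, dtype=np.float64) * span + self.minimum


@dataclass
class LatentThermomics:
    codes: np.ndarray                       # n_subjects x bottleneck
    scaler: MinMaxScaler | None = None
    loss_history: dict = field(default_factory=lambda: {"train": [], "val": []})
    subject_ids: list[str] = field(default_factory=list)


def bce_loss(y: np.ndarray, p: np.ndarray) -> float:
    """Mean binary cross-entropy; p is clipped to [eps, 1 - eps], eps=1e-7."""
    y = np.asarray(y, dtype=np.float64).ravel()
    p = np.asarray(p, dtype=np.float64).ravel()
    if y.shape != p.shape:
        raise ValidationError(f"length mismatch: y has {y.size}, p has {p.size}")
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def scale_features(raw: np.ndarray) -> tuple[np.ndarray, MinMaxScaler]:
    """Min-max scale a feature table (rows = subjects) to [0, 1]."""
    X = np.asarray(raw, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValidationError("feature table must be a non-empty 2-D array")
    if X.shape[0] < 2:
        raise ValidationError("need >= 2 rows for a non-degenerate min/max")
    scaler = MinMaxScaler(minimum=X.min(axis=0), maximum=X.max(axis=0))
    return scaler.transform(X), scaler


class SparseAutoencoder:
    """Untied (optionally tied) dense autoencoder trained with Adam."""

    def __init__(self, spec: AutoencoderSpec):
        self.spec = spec
        self.trained = False
        dims = list(spec.dims)
        widths = dims + dims[-2::-1]            # full mirrored schedule
        rng = np.random.default_rng(spec.seed)
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for din, dout in zip(widths[:-1], widths[1:]):
            self.W.append(rng.normal(0, np.sqrt(2.0 / din), (din, dout))
                          .astype(np.float32))
            self.b.append(np.zeros(dout, np.float32))
        if spec.tied:
            ne = len(dims) - 1
            for i in range(ne):
                self.W[ne + i] = self.W[ne - 1 - i].T.copy()
        self.n_encoder = len(dims) - 1

    # -- forward -----------------------------------------------------------
    def _forward(self, X: np.ndarray) -> list[np.ndarray]:
        acts = [X.astype(np.float32)]
        last = len(self.W) - 1
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = acts[-1] @ W + b
            if i == last:
                a = 1.0 / (1.0 + np.exp(-z))        # sigmoid output
            else:
                a = np.maximum(z, 0.0)              # ReLU hidden
            acts.append(a)
        return acts

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        return self._forward(np.asarray(X))[-1]

    def encode(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[1] != self.spec.input_dim:
            raise ValidationError(
                f"input width {X.shape[-1] if X.ndim == 2 else '?'} != "
                f"spec input dim {self.spec.input_dim}"
            )
        acts = [X.astype(np.float32)]
        for i in range(self.n_encoder):
            acts.append(np.maximum(acts[-1] @ self.W[i] + self.b[i], 0.0))
        return acts[-1].astype(np.float64)

    # -- training ----------------------------------------------------------
    def _grads(self, X: np.ndarray) -> tuple[list, list, float]:
        n = X.shape[0]
        acts = self._forward(X)
        y, p = acts[0], np.clip(acts[-1], _EPS, 1 - _EPS)
        F = X.shape[1]
        loss = bce_loss(y, p)
        h1 = acts[1]                                 # first encoder activation
        loss += self.spec.l1_weight * float(np.abs(h1).mean())
        # dL/dz_out for sigmoid + BCE, averaged over samples and features
        delta = (p - y) / (n * F)
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        for i in range(len(self.W) - 1, -1, -1):
            gW[i] = acts[i].T @ delta
            gb[i] = delta.sum(axis=0)
            if i > 0:
                delta = delta @ self.W[i].T
                if i == 1:                           # l1 on h1, subgradient
                    delta = delta + self.spec.l1_weight * np.sign(h1) / (n * h1.shape[1])
                delta = delta * (acts[i] > 0)        # ReLU mask
        return gW, gb, loss

    def fit(self, X: np.ndarray, cfg: TrainConfig) -> dict:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 2 or X.shape[1] != self.spec.input_dim:
            raise ValidationError(
                f"feature width {X.shape[-1] if X.ndim == 2 else '?'} != "
                f"spec input dim {self.spec.input_dim}"
            )
        if X.min() < -1e-9 or X.max() > 1 + 1e-9:
            raise ValidationError("features must be scaled to [0, 1] (scale_features)")
        rng = np.random.default_rng(self.spec.seed + 1)
        n = X.shape[0]
        n_val = int(round(cfg.validation_fraction * n))
        perm = rng.permutation(n)
        val, train = X[perm[:n_val]], X[perm[n_val:]]
        if train.shape[0] == 0:
            raise ValidationError("no training rows left after validation split")

        mW = [np.zeros_like(w) for w in self.W]
        vW = [np.zeros_like(w) for w in self.W]
        mb = [np.zeros_like(b) for b in self.b]
        vb = [np.zeros_like(b) for b in self.b]
        history = {"train": [], "val": []}
        t = 0
        for _ in range(cfg.epochs):
            order = rng.permutation(train.shape[0])
            epoch_loss, n_batches = 0.0, 0
            for start in range(0, train.shape[0], cfg.batch_size):
                batch = train[order[start:start + cfg.batch_size]]
                gW, gb, loss = self._grads(batch)
                if self.spec.tied:
                    # share gradients so W_dec stays the transpose of W_enc
                    ne = self.n_encoder
                    for i in range(ne):
                        j = 2 * ne - 1 - i
                        g = gW[i] + gW[j].T
                        gW[i], gW[j] = g, g.T
                if not np.isfinite(loss):
                    raise ValidationError(
                        "training diverged (loss is NaN/Inf); lower the learning rate"
                    )
                epoch_loss += loss
                n_batches += 1
                t += 1
                lr_t = cfg.learning_rate * np.sqrt(1 - cfg.beta2**t) / (1 - cfg.beta1**t)
                for i in range(len(self.W)):
                    mW[i] = cfg.beta1 * mW[i] + (1 - cfg.beta1) * gW[i]
                    vW[i] = cfg.beta2 * vW[i] + (1 - cfg.beta2) * gW[i] ** 2
                    self.W[i] -= lr_t * mW[i] / (np.sqrt(vW[i]) + 1e-8)
                    mb[i] = cfg.beta1 * mb[i] + (1 - cfg.beta1) * gb[i]
                    vb[i] = cfg.beta2 * vb[i] + (1 - cfg.beta2) * gb[i] ** 2
                    self.b[i] -= lr_t * mb[i] / (np.sqrt(vb[i]) + 1e-8)
            history["train"].append(epoch_loss / max(n_batches, 1))
            if n_val:
                history["val"].append(bce_loss(val, self.reconstruct(val)))
        self.trained = True
        return history


def train_autoencoder(
    features: np.ndarray,
    spec: AutoencoderSpec | None = None,
    cfg: TrainConfig | None = None,
    scaler: MinMaxScaler | None = None,
    subject_ids: list[str] | None = None,
) -> tuple[SparseAutoencoder, LatentThermomics]:
    """Train on a [0, 1]-scaled feature table; return model + latent codes."""
    spec = spec or AutoencoderSpec()
    cfg = cfg or TrainConfig()
    model = SparseAutoencoder(spec)
    history = model.fit(features, cfg)
    codes = model.encode(features)
    latent = LatentThermomics(codes=codes, scaler=scaler, loss_history=history,
                              subject_ids=list(subject_ids or []))
    return model, latent


def encode(model: SparseAutoencoder, features: np.ndarray) -> np.ndarray:
    """Deterministic forward encoding through the bottleneck."""
    if not model.trained:
        raise ValidationError("model has not been trained; call train_autoencoder")
    return model.encode(features)
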
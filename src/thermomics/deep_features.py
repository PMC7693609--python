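"""ResNet-50 backbone as a declarative layer table + NumPy inference.

The backbone is described by an explicit ordered table of layer
descriptors (a small dataflow graph), from which both the exact parameter
counts and a deterministic forward pass are derived. The canonical table
is the published 50-layer residual ImageNet configuration with its
1000-class head.

Parameter-counting convention (the only one reproducing the canonical
totals of 25,583,592 trainable / 53,120 non-trainable):

* convolutions carry biases;
* batch-norm scale (gamma) and offset (beta) are trainable;
* batch-norm moving mean and moving variance are non-trainable
  (2 per channel);
* the dense head carries biases.

Feature extraction taps the global-average-pool output (2048-d), dropping
the classification head. No deep-learning framework is required: the
forward pass (im2col convolutions, inference-mode batch norm) runs in
NumPy and is deterministic — byte-identical inputs give byte-identical
outputs. Weights are either seeded-random (He initialization; the test
and phantom path) or loaded from a user-supplied ``.npz`` archive of
pretrained arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .lowrank import Avatar

__all__ = [
    "LayerSpec",
    "BackboneSpec",
    "FeatureVector",
    "canonical_resnet50_spec",
    "dense_schedule_spec",
    "count_parameters",
    "Backbone",
    "extract_features",
]

_BN_EPS = 1e-5

# Channel mean/std of the RGB pretraining corpus, applied only when
# pretrained weights are loaded (identity scaling for seeded_random).
_IMAGENET_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
_IMAGENET_STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)


@dataclass(frozen=True)
class LayerSpec:
    """One layer descriptor in the backbone table."""

    name: str
    kind: str                      # conv|batchnorm|relu|maxpool|add|global_avg_pool|dense|input
    inputs: tuple[str, ...] = ()
    in_ch: int = 0
    out_ch: int = 0
    kernel: int = 0
    stride: int = 1
    pad: int = 0
    bias: bool = True
    in_dim: int = 0
    out_dim: int = 0


@dataclass
class BackboneSpec:
    layers: list[LayerSpec]
    input_side: int = 224
    input_channels: int = 3
    feature_dim: int = 2048
    feature_tap: str = "avg_pool"

    def layer(self, name: str) -> LayerSpec:
        for l in self.layers:
            if l.name == name:
                return l
        raise KeyError(name)


@dataclass
class FeatureVector:
    values: np.ndarray
    subject_id: str = ""
    method: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("feature vector contains non-finite values")


def canonical_resnet50_spec() -> BackboneSpec:
    """The published ResNet-50 ImageNet layer table (with 1000-class head).

    Stem: 7x7/2 conv to 64 channels, batch norm, ReLU, 3x3/2 max pool.
    Four bottleneck stages of (3, 4, 6, 3) blocks with mid widths
    (64, 128, 256, 512); every block is 1x1 -> 3x3 -> 1x1 (x4 expansion),
    each convolution followed by batch norm; the first block of each stage
    carries a projection shortcut (1x1 conv + batch norm), strided for
    stages 2-4. Global average pool then a 1000-way dense head.
    """
    L: list[LayerSpec] = [LayerSpec("input", "input")]

    def conv(name, src, cin, cout, k, s, p):
        L.append(LayerSpec(name, "conv", (src,), in_ch=cin, out_ch=cout,
                           kernel=k, stride=s, pad=p, bias=True))
        L.append(LayerSpec(f"bn_{name}", "batchnorm", (name,), out_ch=cout))
        return f"bn_{name}"

    def relu(name, src):
        L.append(LayerSpec(name, "relu", (src,)))
        return name

    top = conv("conv1", "input", 3, 64, 7, 2, 3)
    top = relu("conv1_relu", top)
    L.append(LayerSpec("pool1", "maxpool", (top,), kernel=3, stride=2, pad=1))
    top = "pool1"

    cin = 64
    for stage, (mid, blocks) in enumerate(
            [(64, 3), (128, 4), (256, 6), (512, 3)], start=2):
        cout = 4 * mid
        for b in range(1, blocks + 1):
            tag = f"s{stage}b{b}"
            stride = 2 if (b == 1 and stage > 2) else 1
            if b == 1:
                shortcut = conv(f"{tag}_proj", top, cin, cout, 1, stride, 0)
            else:
                shortcut = top
            x = conv(f"{tag}_c1", top, cin, mid, 1, stride, 0)
            x = relu(f"{tag}_r1", x)
            x = conv(f"{tag}_c2", x, mid, mid, 3, 1, 1)
            x = relu(f"{tag}_r2", x)
            x = conv(f"{tag}_c3", x, mid, cout, 1, 1, 0)
            L.append(LayerSpec(f"{tag}_add", "add", (x, shortcut)))
            top = relu(f"{tag}_out", f"{tag}_add")
            cin = cout

    L.append(LayerSpec("avg_pool", "global_avg_pool", (top,), out_ch=2048))
    L.append(LayerSpec("fc1000", "dense", ("avg_pool",), in_dim=2048,
                       out_dim=1000, bias=True))
    return BackboneSpec(layers=L)


def dense_schedule_spec(dims, bias: bool = True) -> BackboneSpec:
    """A plain dense stack (e.g. an autoencoder schedule) for counting."""
    L = [LayerSpec("input", "input")]
    prev = "input"
    for i in range(len(dims) - 1):
        L.append(LayerSpec(f"dense{i}", "dense", (prev,), in_dim=int(dims[i]),
                           out_dim=int(dims[i + 1]), bias=bias))
        prev = f"dense{i}"
    return BackboneSpec(layers=L, input_side=0, input_channels=0,
                        feature_dim=int(dims[-1]), feature_tap=prev)


def count_parameters(spec: BackboneSpec) -> tuple[int, int]:
    """Closed-form (trainable, non_trainable) parameter counts.

    Additive over layers and invariant to table order; no network is
    instantiated.
    """
    trainable = 0
    non_trainable = 0
    for l in spec.layers:
        if l.kind == "conv":
            if l.kernel <= 0 or l.in_ch <= 0 or l.out_ch <= 0:
                raise ValidationError(f"malformed conv layer {l.name!r}")
            trainable += l.kernel * l.kernel * l.in_ch * l.out_ch
            if l.bias:
                trainable += l.out_ch
        elif l.kind == "batchnorm":
            if l.out_ch <= 0:
                raise ValidationError(f"malformed batchnorm layer {l.name!r}")
            trainable += 2 * l.out_ch          # gamma, beta
            non_trainable += 2 * l.out_ch      # moving mean, moving variance
        elif l.kind == "dense":
            if l.in_dim <= 0 or l.out_dim <= 0:
                raise ValidationError(f"malformed dense layer {l.name!r}")
            trainable += l.in_dim * l.out_dim
            if l.bias:
                trainable += l.out_dim
    return trainable, non_trainable


# ---------------------------------------------------------------------------
# NumPy realization
# ---------------------------------------------------------------------------

def _conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray,
            stride: int, pad: int) -> np.ndarray:
    """im2col convolution; x is (C, H, W), w is (O, C, k, k)."""
    O, C, kh, kw = w.shape
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(1, 2))
    win = win[:, ::stride, ::stride]                 # C, Ho, Wo, kh, kw
    _, Ho, Wo, _, _ = win.shape
    cols = win.transpose(1, 2, 0, 3, 4).reshape(Ho * Wo, C * kh * kw)
    out = cols @ w.reshape(O, -1).T.astype(x.dtype)
    out += b.astype(x.dtype)
    return np.ascontiguousarray(out.T.reshape(O, Ho, Wo))


def _maxpool2d(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad)),
                   constant_values=-np.inf)
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(1, 2))
    win = win[:, ::stride, ::stride]
    return win.max(axis=(3, 4))


class Backbone:
    """A realized network interpreting a :class:`BackboneSpec`.

    ``weights="seeded_random"``: He-normal convolution/dense kernels from
    ``seed``, zero biases, identity batch-norm statistics — fully offline
    and deterministic. ``weights="imagenet"``: arrays loaded from a local
    ``.npz`` checkpoint (keys ``<layer>/kernel``, ``<layer>/bias``,
    ``<layer>/gamma`` ...); input is then standardized with the
    pretraining-corpus channel statistics.
    """

    def __init__(self, spec: BackboneSpec | None = None,
                 weights: str = "seeded_random", seed: int = 0,
                 weights_path=None):
        self.spec = spec or canonical_resnet50_spec()
        self.weights_mode = weights
        self.seed = seed
        self.params: dict[str, dict[str, np.ndarray]] = {}
        if weights == "seeded_random":
            self._init_random(np.random.default_rng(seed))
        elif weights == "imagenet":
            if weights_path is None:
                raise ValidationError(
                    "weights='imagenet' needs weights_path pointing to a local "
                    ".npz checkpoint; no download is performed"
                )
            self._load_npz(weights_path)
        else:
            raise ValidationError(f"unknown weights mode {weights!r}")

    def _init_random(self, rng: np.random.Generator) -> None:
        for l in self.spec.layers:
            if l.kind == "conv":
                fan_in = l.kernel * l.kernel * l.in_ch
                self.params[l.name] = {
                    "kernel": rng.normal(0, np.sqrt(2.0 / fan_in),
                                         (l.out_ch, l.in_ch, l.kernel, l.kernel)
                                         ).astype(np.float32),
                    "bias": np.zeros(l.out_ch, np.float32),
                }
            elif l.kind == "batchnorm":
                self.params[l.name] = {
                    "gamma": np.ones(l.out_ch, np.float32),
                    "beta": np.zeros(l.out_ch, np.float32),
                    "moving_mean": np.zeros(l.out_ch, np.float32),
                    "moving_var": np.ones(l.out_ch, np.float32),
                }
            elif l.kind == "dense":
                self.params[l.name] = {
                    "kernel": rng.normal(0, np.sqrt(2.0 / l.in_dim),
                                         (l.in_dim, l.out_dim)).astype(np.float32),
                    "bias": np.zeros(l.out_dim, np.float32),
                }

    def _load_npz(self, path) -> None:
        arrays = np.load(path)
        for l in self.spec.layers:
            if l.kind in ("conv", "batchnorm", "dense"):
                keys = {"conv": ("kernel", "bias"), "dense": ("kernel", "bias"),
                        "batchnorm": ("gamma", "beta", "moving_mean", "moving_var")}[l.kind]
                try:
                    self.params[l.name] = {
                        k: np.asarray(arrays[f"{l.name}/{k}"], np.float32) for k in keys
                    }
                except KeyError as e:
                    raise ValidationError(
                        f"checkpoint missing array {e} for layer {l.name!r}") from e

    def forward(self, image: np.ndarray, tap: str | None = None) -> np.ndarray:
        """Deterministic inference pass; returns the ``tap`` layer output.

        ``image`` is (side, side, 3) in [0, 1]; defaults to the spec's
        feature tap (the 2048-d global-average-pool activations).
        """
        tap = tap or self.spec.feature_tap
        img = np.asarray(image, dtype=np.float32)
        if img.shape != (self.spec.input_side, self.spec.input_side,
                         self.spec.input_channels):
            raise ValidationError(
                f"input shape {img.shape} does not match backbone input "
                f"({self.spec.input_side}, {self.spec.input_side}, "
                f"{self.spec.input_channels}); use make_avatar(side="
                f"{self.spec.input_side})"
            )
        if self.weights_mode == "imagenet":
            img = (img - _IMAGENET_MEAN) / _IMAGENET_STD
        x = img.transpose(2, 0, 1)                   # CHW

        # reference counts so intermediates are freed as consumed
        consumers: dict[str, int] = {}
        for l in self.spec.layers:
            for src in l.inputs:
                consumers[src] = consumers.get(src, 0) + 1
        consumers[tap] = consumers.get(tap, 0) + 1

        cache: dict[str, np.ndarray] = {"input": x}

        def take(name: str) -> np.ndarray:
            v = cache[name]
            consumers[name] -= 1
            if consumers[name] == 0 and name != tap:
                del cache[name]
            return v

        for l in self.spec.layers:
            if l.kind == "input":
                continue
            if l.name == tap and tap in cache:
                break
            if l.kind == "conv":
                p = self.params[l.name]
                out = _conv2d(take(l.inputs[0]), p["kernel"], p["bias"],
                              l.stride, l.pad)
            elif l.kind == "batchnorm":
                p = self.params[l.name]
                scale = p["gamma"] / np.sqrt(p["moving_var"] + _BN_EPS)
                shift = p["beta"] - p["moving_mean"] * scale
                out = take(l.inputs[0]) * scale[:, None, None] + shift[:, None, None]
            elif l.kind == "relu":
                out = np.maximum(take(l.inputs[0]), 0.0)
            elif l.kind == "maxpool":
                out = _maxpool2d(take(l.inputs[0]), l.kernel, l.stride, l.pad)
            elif l.kind == "add":
                a, b = take(l.inputs[0]), take(l.inputs[1])
                if a.shape != b.shape:
                    raise ValidationError(
                        f"residual add {l.name!r}: shape mismatch {a.shape} vs {b.shape}"
                    )
                out = a + b
            elif l.kind == "global_avg_pool":
                out = take(l.inputs[0]).mean(axis=(1, 2))
            elif l.kind == "dense":
                p = self.params[l.name]
                out = take(l.inputs[0]) @ p["kernel"] + p["bias"]
            else:
                raise ValidationError(f"unknown layer kind {l.kind!r}")
            cache[l.name] = out
            if l.name == tap:
                break
        return cache[tap]


def extract_features(avatar: Avatar, backbone: Backbone) -> FeatureVector:
    """2048-d deep thermomic features: global-average-pool activations."""
    values = backbone.forward(avatar.image)
    return FeatureVector(values=values, method="")
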
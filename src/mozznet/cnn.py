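"""The tiny 3-class spectrogram CNN: build, train, quantize, run.

Architecture (default config): a 49x40x1 log-mel image passes through
three valid 5x4 convolutions with 8 channels (ReLU), 2x2 max pooling
after the first two, a 64-unit fully connected layer (ReLU) and a 3-way
output (Silence, Noise, Mosquito).  Two printed-size conventions of the
deployed model are honoured exactly:

* the first convolution's output is cropped by one column (45x37 ->
  45x36) so every downstream tensor size and parameter count matches the
  deployed accounting (18,363 parameters in total);
* 2x2 max pooling uses ceil semantics (odd edges padded with -inf), the
  only convention that yields the 45->23, 19->10 and 15->8 reductions.

Inference emits a quantized score vector over (Silence, Noise, Mosquito)
whose components are non-negative integers summing to exactly 256
(softmax scaled by 256 with largest-remainder rounding).

Everything — forward pass, backprop, SGD with dropout — is implemented
directly on numpy; the model is small enough (≈18k parameters) that no
framework is needed.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, asdict, field

import numpy as np

from .features import Spectrogram


# ---------------------------------------------------------------- config


@dataclass
class ModelConfig:
    input_h: int = 49
    input_w: int = 40
    in_channels: int = 1
    conv_channels: int = 8
    kernel_h: int = 5
    kernel_w: int = 4
    c1_crop_cols: int = 1  # reconciles valid-conv 45x37 with the deployed 45x36
    fc_units: int = 64
    n_classes: int = 3
    dropout_rate: float = 0.5
    learning_rate: float = 0.02
    batch_size: int = 32
    init_std: float = 0.0  # 0 -> fan-in (He) scaling; >0 -> fixed std
    seed: int = 0

    def shape_chain(self) -> list[tuple[str, tuple[int, int, int]]]:
        """(layer name, output tensor h x w x c) for every stage."""

        def conv(h, w):
            return h - self.kernel_h + 1, w - self.kernel_w + 1

        def pool(h, w):  # ceil semantics
            return -(-h // 2), -(-w // 2)

        c = self.conv_channels
        h, w = self.input_h, self.input_w
        chain = [("Input", (h, w, self.in_channels))]
        h, w = conv(h, w)
        w -= self.c1_crop_cols
        if h <= 0 or w <= 0:
            raise ValueError("C1 output collapsed: kernel larger than input")
        chain.append(("C1", (h, w, c)))
        h, w = pool(h, w)
        chain.append(("S1", (h, w, c)))
        h, w = conv(h, w)
        if h <= 0 or w <= 0:
            raise ValueError("C2 output collapsed")
        chain.append(("C2", (h, w, c)))
        h, w = pool(h, w)
        chain.append(("S2", (h, w, c)))
        h, w = conv(h, w)
        if h <= 0 or w <= 0:
            raise ValueError("C3 output collapsed")
        chain.append(("C3", (h, w, c)))
        chain.append(("FC", (self.fc_units, 1, 1)))
        chain.append(("Output", (self.n_classes, 1, 1)))
        return chain


@dataclass
class LayerReport:
    name: str
    tensor_size: tuple
    n_weights: int
    n_biases: int

    @property
    def n_params(self) -> int:
        return self.n_weights + self.n_biases


# ------------------------------------------------------------ score vector


@dataclass(frozen=True)
class ScoreVector:
    """Quantized class scores; components are >= 0 and sum to exactly 256."""

    silence: int
    noise: int
    mosquito: int

    def __post_init__(self):
        total = self.silence + self.noise + self.mosquito
        if total != 256 or min(self.silence, self.noise, self.mosquito) < 0:
            raise ValueError(f"scores must be non-negative and sum to 256, got {self}")

    def as_array(self) -> np.ndarray:
        return np.array([self.silence, self.noise, self.mosquito], dtype=np.int64)

    def argmax(self) -> int:
        """Index of the winning class; ties resolve to the earlier class."""
        return int(np.argmax(self.as_array()))


def quantize_scores(logits: np.ndarray) -> ScoreVector:
    """Softmax -> x256 -> largest-remainder integer rounding (sum exactly 256)."""
    logits = np.asarray(logits, dtype=np.float64)
    if logits.shape != (3,):
        raise ValueError("expected 3 logits")
    z = logits - np.max(logits)
    p = np.exp(z)
    p /= p.sum()
    scaled = p * 256.0
    floors = np.floor(scaled).astype(np.int64)
    remainder = int(256 - floors.sum())
    order = np.argsort(-(scaled - floors), kind="stable")
    for i in range(remainder):
        floors[order[i]] += 1
    return ScoreVector(int(floors[0]), int(floors[1]), int(floors[2]))


# ------------------------------------------------------------- primitives


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """Valid 2-D convolution (cross-correlation). x: (B,H,W,C); w: (kh,kw,C,D)."""
    kh, kw = w.shape[:2]
    patches = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(1, 2))
    # patches: (B, Ho, Wo, C, kh, kw)
    y = np.einsum("bhwckl,klcd->bhwd", patches, w, optimize=True) + b
    return y, patches


def _conv_backward(dy, patches, w, x_shape):
    kh, kw = w.shape[:2]
    dw = np.einsum("bhwckl,bhwd->klcd", patches, dy, optimize=True)
    db = dy.sum(axis=(0, 1, 2))
    dx = np.zeros(x_shape)
    ho, wo = dy.shape[1], dy.shape[2]
    for i in range(kh):
        for j in range(kw):
            dx[:, i : i + ho, j : j + wo, :] += np.einsum(
                "bhwd,cd->bhwc", dy, w[i, j], optimize=True
            )
    return dx, dw, db


def _pool_forward(x: np.ndarray):
    """2x2 max pool, stride 2, ceil semantics via -inf edge padding."""
    b, h, w, c = x.shape
    ph, pw = -(-h // 2) * 2, -(-w // 2) * 2
    padded = np.full((b, ph, pw, c), -np.inf)
    padded[:, :h, :w, :] = x
    tiles = padded.reshape(b, ph // 2, 2, pw // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
    flat = tiles.reshape(b, ph // 2, pw // 2, c, 4)
    idx = np.argmax(flat, axis=-1)
    y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    return y, (idx, x.shape)


def _pool_backward(dy, cache):
    idx, (b, h, w, c) = cache
    ph, pw = -(-h // 2) * 2, -(-w // 2) * 2
    dflat = np.zeros((b, ph // 2, pw // 2, c, 4))
    np.put_along_axis(dflat, idx[..., None], dy[..., None], axis=-1)
    dpadded = dflat.reshape(b, ph // 2, pw // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
    dpadded = dpadded.reshape(b, ph, pw, c)
    return dpadded[:, :h, :w, :]


# ------------------------------------------------------------------ model


_WEIGHT_KEYS = ("w1", "b1", "w2", "b2", "w3", "b3", "w_fc", "b_fc", "w_out", "b_out")


class TinyConvNet:
    """The layered computation graph plus its parameters and RNG."""

    def __init__(self, config: ModelConfig | None = None):
        self.config = config or ModelConfig()
        self.rng = np.random.default_rng(self.config.seed)
        cfg = self.config
        chain = dict((name, shape) for name, shape in cfg.shape_chain())
        self._chain = cfg.shape_chain()
        c = cfg.conv_channels
        flat = int(np.prod(chain["C3"]))
        k = (cfg.kernel_h, cfg.kernel_w)
        self.params = {
            "w1": self._init((*k, cfg.in_channels, c)),
            "b1": np.zeros(c),
            "w2": self._init((*k, c, c)),
            "b2": np.zeros(c),
            "w3": self._init((*k, c, c)),
            "b3": np.zeros(c),
            "w_fc": self._init((flat, cfg.fc_units)),
            "b_fc": np.zeros(cfg.fc_units),
            "w_out": self._init((cfg.fc_units, cfg.n_classes)),
            "b_out": np.zeros(cfg.n_classes),
        }
        self.trained = False

    def _init(self, shape) -> np.ndarray:
        """Truncated-normal init (resample beyond 2 sigma).

        ``init_std`` > 0 is used directly; ``init_std`` = 0 selects
        fan-in scaling (std = sqrt(2 / fan_in), the ReLU-preserving
        choice), which the default config uses — a fixed small std
        leaves this depth of ReLU stack too close to zero to train in
        the short 240-step budget.
        """
        std = self.config.init_std
        if not std:
            fan_in = int(np.prod(shape[:-1]))
            std = float(np.sqrt(2.0 / fan_in))
        out = self.rng.standard_normal(shape)
        bad = np.abs(out) > 2.0
        while np.any(bad):
            out[bad] = self.rng.standard_normal(int(bad.sum()))
            bad = np.abs(out) > 2.0
        return out * std

    # -- forward / backward

    #: fixed affine input normalization (uint8 image -> roughly zero
    #: mean, unit variance for typical log-mel images)
    INPUT_OFFSET = 60.0
    INPUT_SCALE = 35.0

    @classmethod
    def _normalize(cls, images: np.ndarray) -> np.ndarray:
        """uint8 image(s) -> centered floats, shape (B, H, W, 1)."""
        x = np.asarray(images, dtype=np.float64)
        if x.ndim == 2:
            x = x[None]
        return ((x - cls.INPUT_OFFSET) / cls.INPUT_SCALE)[..., None]

    def forward(self, images: np.ndarray, train: bool = False, rng=None):
        """Logits (B, n_classes); caches intermediates when training."""
        cfg = self.config
        p = self.params
        x = self._normalize(images)
        if x.shape[1:3] != (cfg.input_h, cfg.input_w):
            raise ValueError(
                f"input must be {cfg.input_h}x{cfg.input_w}, got {x.shape[1:3]}"
            )
        cache = {"x": x}
        keep = 1.0 - cfg.dropout_rate

        def dropout(h, name):
            if not train or cfg.dropout_rate == 0.0:
                return h
            mask = (rng.random(h.shape) < keep) / keep
            cache[name] = mask
            return h * mask

        z1, cache["p1"] = _conv_forward(x, p["w1"], p["b1"])
        if cfg.c1_crop_cols:
            z1 = z1[:, :, : z1.shape[2] - cfg.c1_crop_cols, :]
        a1 = np.maximum(z1, 0.0)
        cache["z1"], _ = z1, None
        d1 = dropout(a1, "m1")
        s1, cache["pc1"] = _pool_forward(d1)

        z2, cache["p2"] = _conv_forward(s1, p["w2"], p["b2"])
        a2 = np.maximum(z2, 0.0)
        cache["z2"], cache["s1"] = z2, s1
        d2 = dropout(a2, "m2")
        s2, cache["pc2"] = _pool_forward(d2)

        z3, cache["p3"] = _conv_forward(s2, p["w3"], p["b3"])
        a3 = np.maximum(z3, 0.0)
        cache["z3"], cache["s2"] = z3, s2
        d3 = dropout(a3, "m3")

        flat = d3.reshape(d3.shape[0], -1)
        zf = flat @ p["w_fc"] + p["b_fc"]
        af = np.maximum(zf, 0.0)
        logits = af @ p["w_out"] + p["b_out"]
        cache.update(flat=flat, zf=zf, af=af, d3_shape=d3.shape)
        self._cache = cache
        return logits

    def backward(self, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        cfg = self.config
        p, c = self.params, self._cache
        g = {}
        g["w_out"] = c["af"].T @ dlogits
        g["b_out"] = dlogits.sum(axis=0)
        daf = dlogits @ p["w_out"].T
        dzf = daf * (c["zf"] > 0)
        g["w_fc"] = c["flat"].T @ dzf
        g["b_fc"] = dzf.sum(axis=0)
        dflat = dzf @ p["w_fc"].T
        dd3 = dflat.reshape(c["d3_shape"])
        if "m3" in c:
            dd3 = dd3 * c["m3"]
        dz3 = dd3 * (c["z3"] > 0)
        ds2, g["w3"], g["b3"] = _conv_backward(dz3, c["p3"], p["w3"], c["s2"].shape)

        dd2 = _pool_backward(ds2, c["pc2"])
        if "m2" in c:
            dd2 = dd2 * c["m2"]
        dz2 = dd2 * (c["z2"] > 0)
        ds1, g["w2"], g["b2"] = _conv_backward(dz2, c["p2"], p["w2"], c["s1"].shape)

        dd1 = _pool_backward(ds1, c["pc1"])
        if "m1" in c:
            dd1 = dd1 * c["m1"]
        dz1 = dd1 * (c["z1"] > 0)
        if cfg.c1_crop_cols:  # cropped columns received no gradient
            pad = np.zeros(dz1.shape[:2] + (cfg.c1_crop_cols,) + dz1.shape[3:])
            dz1 = np.concatenate([dz1, pad], axis=2)
        _, g["w1"], g["b1"] = _conv_backward(dz1, c["p1"], p["w1"], c["x"].shape)
        return g

    def snapshot(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}


def build_model(config: ModelConfig | None = None) -> TinyConvNet:
    return TinyConvNet(config)


def count_parameters(model: TinyConvNet) -> tuple[list[LayerReport], int, int, int]:
    """Per-layer closed-form weight/bias counts and (weights, biases, total)."""
    cfg = model.config
    chain = cfg.shape_chain()
    sizes = dict(chain)
    kk = cfg.kernel_h * cfg.kernel_w
    c = cfg.conv_channels
    flat = int(np.prod(sizes["C3"]))
    counts = {
        "Input": (0, 0),
        "C1": (kk * cfg.in_channels * c, c),
        "S1": (0, 0),
        "C2": (kk * c * c, c),
        "S2": (0, 0),
        "C3": (kk * c * c, c),
        "FC": (flat * cfg.fc_units, cfg.fc_units),
        "Output": (cfg.fc_units * cfg.n_classes, cfg.n_classes),
    }
    reports = [LayerReport(name, shape, *counts[name]) for name, shape in chain]
    n_w = sum(r.n_weights for r in reports)
    n_b = sum(r.n_biases for r in reports)
    return reports, n_w, n_b, n_w + n_b


# --------------------------------------------------------------- training


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean loss and d(loss)/d(logits) for integer labels."""
    z = logits - logits.max(axis=1, keepdims=True)
    expz = np.exp(z)
    p = expz / expz.sum(axis=1, keepdims=True)
    n = len(labels)
    loss = -np.mean(np.log(p[np.arange(n), labels] + 1e-300))
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


def train(
    model: TinyConvNet,
    images: np.ndarray,
    labels: np.ndarray,
    steps: int = 750,
    checkpoint_every: int = 100,
):
    """SGD training with dropout; deterministic given the model config seed.

    ``steps * batch_size`` is the number of sample presentations (the
    default 750 x 32 ≈ 24,000).  Returns (model, trace, checkpoints)
    where trace has one (step, loss, batch accuracy) row per step and a
    parameter snapshot is kept every ``checkpoint_every`` steps.
    """
    images = np.asarray(images)
    labels = np.asarray(labels, dtype=np.int64)
    if len(images) == 0:
        raise ValueError("empty dataset")
    if len(np.unique(labels)) < model.config.n_classes:
        raise ValueError("training labels must cover all classes")
    cfg = model.config
    rng = np.random.default_rng(cfg.seed + 1)
    trace, checkpoints = [], []
    for step in range(1, steps + 1):
        idx = rng.choice(len(images), size=min(cfg.batch_size, len(images)), replace=False)
        logits = model.forward(images[idx], train=True, rng=rng)
        loss, dlogits = softmax_cross_entropy(logits, labels[idx])
        grads = model.backward(dlogits)
        for k in model.params:
            model.params[k] -= cfg.learning_rate * grads[k]
        acc = float(np.mean(np.argmax(logits, axis=1) == labels[idx]))
        trace.append({"step": step, "loss": float(loss), "batch_accuracy": acc})
        if checkpoint_every and step % checkpoint_every == 0:
            checkpoints.append((step, model.snapshot()))
    model.trained = steps > 0 or model.trained
    return model, trace, checkpoints


def predict_logits(model: TinyConvNet, images: np.ndarray) -> np.ndarray:
    """Inference-mode logits (dropout off, deterministic)."""
    return model.forward(images, train=False)


def classify(model: TinyConvNet, spec) -> ScoreVector:
    """Quantized score vector for one spectrogram (or raw 49x40 image)."""
    if not model.trained:
        raise RuntimeError("model has not been trained")
    image = spec.image if isinstance(spec, Spectrogram) else np.asarray(spec)
    logits = model.forward(image[None] if image.ndim == 2 else image, train=False)
    return quantize_scores(logits[0])


def accuracy(model: TinyConvNet, images: np.ndarray, labels: np.ndarray) -> float:
    logits = predict_logits(model, images)
    return float(np.mean(np.argmax(logits, axis=1) == np.asarray(labels)))


# ------------------------------------------------------------ persistence


def save_model(model: TinyConvNet, path) -> None:
    """Flat-file save: JSON config header + weight arrays in layer order."""
    arrays = {k: model.params[k] for k in _WEIGHT_KEYS}
    np.savez(path, __config__=json.dumps(asdict(model.config)), **arrays)


def load_model(path) -> TinyConvNet:
    with np.load(path, allow_pickle=False) as data:
        cfg = ModelConfig(**json.loads(str(data["__config__"])))
        model = TinyConvNet(cfg)
        for k in _WEIGHT_KEYS:
            model.params[k] = data[k]
    model.trained = True
    return model


def export_byte_array(model: TinyConvNet) -> bytes:
    """Per-layer affine uint8 quantization of all weights, concatenated.

    Mirrors a flat on-device embedding of the model: for each parameter
    array in layer order, 8 bytes of float32 (min, max) followed by the
    uint8-quantized values.  Content layout only; no device tooling.
    """
    out = io.BytesIO()
    for k in _WEIGHT_KEYS:
        a = model.params[k].astype(np.float64)
        lo, hi = float(a.min()), float(a.max())
        scale = (hi - lo) or 1.0
        q = np.round((a - lo) / scale * 255.0).astype(np.uint8)
        out.write(np.array([lo, hi], dtype=np.float32).tobytes())
        out.write(q.tobytes())
    return out.getvalue()
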
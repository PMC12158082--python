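"""Convolutional posture classifier over canonical 500x3 frames.

The 500x3 point matrix (lexicographically ordered xyz rows, zero pad
trailing) is treated as a height-500, width-3, single-channel image.
Architecture:

    input 500x3x1
    -> conv 3x3 (16 ch, same padding) -> leaky-ReLU -> maxpool 2x1
    -> conv 3x3 (64 ch, same padding) -> leaky-ReLU -> maxpool 2x1
    -> flatten -> dense 128 -> leaky-ReLU -> dropout 0.5
    -> dense 3 -> softmax

Pooling acts along the point axis only, preserving the 3-wide
coordinate axis.  Training minimizes categorical cross-entropy with
Adam (lr 0.001, batch 32).  Forward, backward and the optimizer are
implemented directly in numpy, which makes training bit-deterministic
under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np

from .core import PostureLabel
from .preprocessing import NormalizedFrame

__all__ = [
    "ModelConfig",
    "PredictionResult",
    "PostureCNN",
    "CLASS_ORDER",
    "build_model",
    "train_model",
    "predict",
    "predict_batch",
    "save_model",
    "load_model",
    "frames_to_tensor",
    "labels_to_ints",
]

#: fixed output-class order of the softmax head
CLASS_ORDER = (PostureLabel.standing, PostureLabel.sitting, PostureLabel.lying)


@dataclass
class ModelConfig:
    """Hyperparameters of the posture CNN.

    The channel counts (16, 64), dropout 0.5, Adam lr 0.001, batch 32
    and the 3-class softmax head are fixed properties of the design;
    kernel size, pooling window, dense width and the leaky-ReLU slope
    are implementation defaults exposed for experimentation.
    """

    conv1_channels: int = 16
    conv2_channels: int = 64
    kernel: tuple[int, int] = (3, 3)
    pool: tuple[int, int] = (2, 1)
    leaky_slope: float = 0.01
    dense_width: int = 128
    dropout_rate: float = 0.5
    n_classes: int = 3
    learning_rate: float = 0.001
    batch_size: int = 32
    epochs: int = 100
    input_points: int = 500
    val_fraction: float = 0.1
    seed: int = 0
    confidence_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.n_classes != 3:
            raise ValueError("the classifier has exactly 3 output classes")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        for name in ("conv1_channels", "conv2_channels", "dense_width",
                     "batch_size", "epochs", "input_points"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass(frozen=True)
class PredictionResult:
    """Softmax probabilities plus the argmax label.  ``label`` becomes
    ``unknown`` when an optional confidence gate is configured and the
    max probability falls below it."""

    probabilities: np.ndarray  # (3,)
    label: PostureLabel
    confidence: float


def _lrelu(x: np.ndarray, a: float) -> np.ndarray:
    return np.where(x > 0, x, a * x)


def _lrelu_grad(x: np.ndarray, a: float) -> np.ndarray:
    return np.where(x > 0, 1.0, a).astype(x.dtype)


def _conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """3x3 'same' convolution via a 9-offset accumulation (fast with BLAS)."""
    B, H, Wd, _ = x.shape
    kh, kw = W.shape[:2]
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    out = np.broadcast_to(b, (B, H, Wd, W.shape[3])).copy()
    for i in range(kh):
        for j in range(kw):
            out += np.tensordot(xp[:, i:i + H, j:j + Wd, :], W[i, j], axes=([3], [0]))
    return out


def _conv_backward(x: np.ndarray, W: np.ndarray, dout: np.ndarray):
    B, H, Wd, _ = x.shape
    kh, kw = W.shape[:2]
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    dxp = np.zeros_like(xp)
    dW = np.zeros_like(W)
    for i in range(kh):
        for j in range(kw):
            patch = xp[:, i:i + H, j:j + Wd, :]
            dW[i, j] = np.tensordot(patch, dout, axes=([0, 1, 2], [0, 1, 2]))
            dxp[:, i:i + H, j:j + Wd, :] += np.tensordot(dout, W[i, j],
                                                         axes=([3], [1]))
    db = dout.sum(axis=(0, 1, 2))
    dx = dxp[:, ph:ph + H, pw:pw + Wd, :]
    return dx, dW, db


def _pool_forward(x: np.ndarray, window: tuple[int, int]):
    B, H, Wd, C = x.shape
    wh, ww = window
    assert H % wh == 0 and Wd % ww == 0, "input not divisible by pool window"
    xr = x.reshape(B, H // wh, wh, Wd // ww, ww, C)
    xr = xr.transpose(0, 1, 3, 5, 2, 4).reshape(B, H // wh, Wd // ww, C, wh * ww)
    idx = xr.argmax(axis=4)
    out = np.take_along_axis(xr, idx[..., None], axis=4)[..., 0]
    return out, idx


def _pool_backward(dout: np.ndarray, idx: np.ndarray, in_shape, window):
    B, H, Wd, C = in_shape
    wh, ww = window
    dxr = np.zeros((B, H // wh, Wd // ww, C, wh * ww), dtype=dout.dtype)
    np.put_along_axis(dxr, idx[..., None], dout[..., None], axis=4)
    dxr = dxr.reshape(B, H // wh, Wd // ww, C, wh, ww).transpose(0, 1, 4, 2, 5, 3)
    return dxr.reshape(B, H, Wd, C)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class PostureCNN:
    """The model: configuration plus parameter arrays (float32)."""

    cfg: ModelConfig
    params: dict = field(default_factory=dict)

    @property
    def flat_features(self) -> int:
        h = self.cfg.input_points
        w = 3
        for _ in range(2):
            h //= self.cfg.pool[0]
            w //= self.cfg.pool[1]
        return h * w * self.cfg.conv2_channels

    def initialize(self) -> None:
        rng = np.random.default_rng(self.cfg.seed)
        kh, kw = self.cfg.kernel
        c1, c2 = self.cfg.conv1_channels, self.cfg.conv2_channels
        d, k = self.cfg.dense_width, self.cfg.n_classes

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), shape).astype(np.float32)

        self.params = {
            "W1": he((kh, kw, 1, c1), kh * kw),
            "b1": np.zeros(c1, dtype=np.float32),
            "W2": he((kh, kw, c1, c2), kh * kw * c1),
            "b2": np.zeros(c2, dtype=np.float32),
            "W3": he((self.flat_features, d), self.flat_features),
            "b3": np.zeros(d, dtype=np.float32),
            "W4": he((d, k), d),
            "b4": np.zeros(k, dtype=np.float32),
        }

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None):
        """Forward pass; returns (probabilities, cache for backward)."""
        cfg, p = self.cfg, self.params
        a = cfg.leaky_slope
        z1 = _conv_forward(x, p["W1"], p["b1"])
        h1 = _lrelu(z1, a)
        p1, idx1 = _pool_forward(h1, cfg.pool)
        z2 = _conv_forward(p1, p["W2"], p["b2"])
        h2 = _lrelu(z2, a)
        p2, idx2 = _pool_forward(h2, cfg.pool)
        flat = p2.reshape(len(x), -1)
        z3 = flat @ p["W3"] + p["b3"]
        h3 = _lrelu(z3, a)
        if train and cfg.dropout_rate > 0:
            assert rng is not None
            mask = (rng.random(h3.shape) >= cfg.dropout_rate).astype(np.float32)
            h3d = h3 * mask / (1.0 - cfg.dropout_rate)
        else:
            mask = None
            h3d = h3
        logits = h3d @ p["W4"] + p["b4"]
        probs = _softmax(logits)
        cache = (x, z1, h1, p1, idx1, z2, h2, p2, idx2, flat, z3, h3, mask, h3d)
        return probs, cache

    def backward(self, probs: np.ndarray, y_onehot: np.ndarray, cache) -> dict:
        cfg, p = self.cfg, self.params
        a = cfg.leaky_slope
        (x, z1, h1, p1, idx1, z2, h2, p2, idx2, flat, z3, h3, mask, h3d) = cache
        B = len(x)
        dlogits = (probs - y_onehot) / B
        grads = {}
        grads["W4"] = h3d.T @ dlogits
        grads["b4"] = dlogits.sum(axis=0)
        dh3d = dlogits @ p["W4"].T
        if mask is not None:
            dh3 = dh3d * mask / (1.0 - cfg.dropout_rate)
        else:
            dh3 = dh3d
        dz3 = dh3 * _lrelu_grad(z3, a)
        grads["W3"] = flat.T @ dz3
        grads["b3"] = dz3.sum(axis=0)
        dflat = dz3 @ p["W3"].T
        dp2 = dflat.reshape(p2.shape)
        dh2 = _pool_backward(dp2, idx2, h2.shape, cfg.pool)
        dz2 = dh2 * _lrelu_grad(z2, a)
        dp1, grads["W2"], grads["b2"] = _conv_backward(p1, p["W2"], dz2)
        dh1 = _pool_backward(dp1, idx1, h1.shape, cfg.pool)
        dz1 = dh1 * _lrelu_grad(z1, a)
        _, grads["W1"], grads["b1"] = _conv_backward(x, p["W1"], dz1)
        return grads


def build_model(cfg: ModelConfig | None = None) -> PostureCNN:
    """Construct and deterministically initialize an untrained model."""
    cfg = cfg or ModelConfig()
    if cfg.input_points % (cfg.pool[0] ** 2) != 0:
        raise ValueError("input_points must be divisible by the pooled windows")
    model = PostureCNN(cfg=cfg)
    model.initialize()
    return model


def frames_to_tensor(frames) -> np.ndarray:
    """Stack NormalizedFrames (or (n,500,3) arrays) into (B, 500, 3, 1)."""
    arrs = [f.points if isinstance(f, NormalizedFrame) else np.asarray(f)
            for f in frames]
    x = np.stack(arrs).astype(np.float32)
    return x[..., None]


def labels_to_ints(labels) -> np.ndarray:
    idx = {c: i for i, c in enumerate(CLASS_ORDER)}
    out = []
    for lab in labels:
        lab = PostureLabel(lab)
        if lab not in idx:
            raise ValueError(f"label {lab} is not a classifier class")
        out.append(idx[lab])
    return np.array(out, dtype=int)


def _ce_loss(probs: np.ndarray, y: np.ndarray) -> float:
    return float(-np.log(np.clip(probs[np.arange(len(y)), y], 1e-12, None)).mean())


def train_model(model: PostureCNN, frames, labels,
                cfg: ModelConfig | None = None) -> dict:
    """Train with Adam on categorical cross-entropy.

    A stratified 90/10 train/validation split (seed-pinned) is held out
    internally; the returned history maps ``train_loss``/``val_loss`` to
    per-epoch values.  Raises on empty data, unknown labels, or a class
    with no samples.
    """
    from sklearn.model_selection import train_test_split

    cfg = cfg or model.cfg
    if len(frames) == 0:
        raise ValueError("empty training set")
    x = frames_to_tensor(frames)
    y = labels_to_ints(labels)
    if len(np.unique(y)) < cfg.n_classes:
        raise ValueError("every posture class needs at least one sample")
    rng = np.random.default_rng(cfg.seed + 1)
    if cfg.val_fraction > 0 and len(x) >= 3 * cfg.n_classes:
        xtr, xva, ytr, yva = train_test_split(
            x, y, test_size=cfg.val_fraction, stratify=y, random_state=cfg.seed % (2**32)
        )
    else:
        xtr, xva, ytr, yva = x, x, y, y

    # Adam state
    m = {k: np.zeros_like(v) for k, v in model.params.items()}
    v = {k: np.zeros_like(vv) for k, vv in model.params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0
    eye = np.eye(cfg.n_classes, dtype=np.float32)
    history = {"train_loss": [], "val_loss": []}
    for _ in range(cfg.epochs):
        order = rng.permutation(len(xtr))
        epoch_losses = []
        for start in range(0, len(xtr), cfg.batch_size):
            sel = order[start:start + cfg.batch_size]
            xb, yb = xtr[sel], ytr[sel]
            probs, cache = model.forward(xb, train=True, rng=rng)
            epoch_losses.append(_ce_loss(probs, yb))
            grads = model.backward(probs, eye[yb], cache)
            t += 1
            corr1 = 1 - beta1 ** t
            corr2 = 1 - beta2 ** t
            for k, g in grads.items():
                m[k] = beta1 * m[k] + (1 - beta1) * g
                v[k] = beta2 * v[k] + (1 - beta2) * g * g
                model.params[k] -= (cfg.learning_rate * (m[k] / corr1)
                                    / (np.sqrt(v[k] / corr2) + eps)).astype(np.float32)
        val_probs = _predict_probs(model, xva)
        history["train_loss"].append(float(np.mean(epoch_losses)))
        history["val_loss"].append(_ce_loss(val_probs, yva))
    return history


def _predict_probs(model: PostureCNN, x: np.ndarray, chunk: int = 256) -> np.ndarray:
    parts = []
    for start in range(0, len(x), chunk):
        probs, _ = model.forward(x[start:start + chunk], train=False)
        parts.append(probs)
    return np.vstack(parts)


def predict_batch(model: PostureCNN, frames) -> list[PredictionResult]:
    """Inference (dropout disabled) over a batch of canonical frames."""
    x = frames_to_tensor(frames)
    probs = _predict_probs(model, x)
    results = []
    thr = model.cfg.confidence_threshold
    for p in probs:
        i = int(p.argmax())
        conf = float(p[i])
        label = CLASS_ORDER[i]
        if thr is not None and conf < thr:
            label = PostureLabel.unknown
        results.append(PredictionResult(probabilities=p, label=label, confidence=conf))
    return results


def predict(model: PostureCNN, frame) -> PredictionResult:
    """Classify one canonical frame."""
    pts = frame.points if isinstance(frame, NormalizedFrame) else np.asarray(frame)
    if pts.shape != (model.cfg.input_points, 3):
        raise ValueError(
            f"expected ({model.cfg.input_points}, 3) input, got {pts.shape}"
        )
    return predict_batch(model, [pts])[0]


def save_model(model: PostureCNN, path) -> None:
    """Persist config + parameters (npz container)."""
    cfg_json = json.dumps(asdict(model.cfg))
    np.savez(path, __config__=np.frombuffer(cfg_json.encode(), dtype=np.uint8),
             **model.params)


def load_model(path) -> PostureCNN:
    """Load a model persisted by :func:`save_model`."""
    try:
        with np.load(path) as data:
            cfg_dict = json.loads(bytes(data["__config__"]).decode())
            for key in ("kernel", "pool"):
                cfg_dict[key] = tuple(cfg_dict[key])
            cfg = ModelConfig(**cfg_dict)
            params = {k: data[k] for k in data.files if k != "__config__"}
    except (OSError, KeyError, ValueError, json.JSONDecodeError) as exc:
        raise ValueError(f"cannot load model from {path}: {exc}") from exc
    return PostureCNN(cfg=cfg, params=params)
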
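"""Sensor-side intake classifier: a small 15-layer CNN on scalogram images.

The network classifies one 192 x 192 x 1 scalogram as intake vs non-intake
and emits the intake-class softmax probability as the sensor confidence
score Ss. Layer composition (15 layers): three convolutional layers, three
ReLU layers, three max-pooling layers, two cross-channel (local response)
normalization layers after the first two conv blocks, one dropout layer, one
fully connected layer, one softmax layer and one classification layer.

The implementation is plain NumPy (im2col convolutions, SGD with momentum,
weighted cross-entropy); at this network size that trains a few hundred
scalograms for the standard 8 epochs in well under CPU-minutes, with bitwise
reproducibility under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.ndimage import correlate1d


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training hyperparameters.

    Only the layer composition, epochs (8) and batch size (32) are fixed by
    the method; filter counts, kernel sizes, pooling, LRN constants, dropout
    rate and the optimizer are package defaults, all exposed here.
    """

    input_shape: tuple[int, int, int] = (192, 192, 1)
    conv_filters: tuple[int, int, int] = (8, 16, 32)
    conv_kernels: tuple[int, int, int] = (5, 3, 3)
    pool_size: int = 2
    pool_stride: int = 2
    lrn_window: int = 5
    lrn_k: float = 1.0
    lrn_alpha: float = 1e-4
    lrn_beta: float = 0.75
    dropout_rate: float = 0.5
    n_classes: int = 2
    epochs: int = 8
    batch_size: int = 32
    learning_rate: float = 0.02
    momentum: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must lie in [0, 1)")
        if len(self.conv_filters) != 3 or len(self.conv_kernels) != 3:
            raise ValueError("exactly three conv blocks are required")
        h, w, c = self.input_shape
        if h % 8 or w % 8:
            raise ValueError("input height/width must be divisible by 8 (three 2x2 pools)")


class _Conv2D:
    """Same-padded stride-1 convolution via im2col."""

    def __init__(self, k: int, c_in: int, c_out: int, rng: np.random.Generator):
        fan_in = k * k * c_in
        self.k = k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, c_out)).astype(
            np.float32
        )
        self.b = np.zeros(c_out, dtype=np.float32)
        self.vW = np.zeros_like(self.W)
        self.vb = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        bsz, h, w, c = x.shape
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        cols = sliding_window_view(xp, (k, k), axis=(1, 2)).reshape(
            bsz * h * w, c * k * k
        )
        self._cols, self._shape = cols, (bsz, h, w, c)
        out = cols @ self.W + self.b
        return out.reshape(bsz, h, w, -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        bsz, h, w, c = self._shape
        k, p = self.k, self.k // 2
        d2 = dout.reshape(bsz * h * w, -1).astype(np.float32)
        self.dW = self._cols.T @ d2
        self.db = d2.sum(axis=0)
        dcols = (d2 @ self.W.T).reshape(bsz, h, w, c, k, k)
        dxp = np.zeros((bsz, h + 2 * p, w + 2 * p, c), dtype=np.float32)
        for di in range(k):
            for dj in range(k):
                dxp[:, di : di + h, dj : dj + w, :] += dcols[:, :, :, :, di, dj]
        self._cols = None
        return dxp[:, p : p + h, p : p + w, :]

    def step(self, lr: float, mu: float) -> None:
        self.vW = mu * self.vW - lr * self.dW
        self.vb = mu * self.vb - lr * self.db
        self.W += self.vW
        self.b += self.vb


class _ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class _LRN:
    """Cross-channel local response normalization.

    b_c = a_c / (k + (alpha / n) * sum_{c' in window(c)} a_{c'}^2)^beta
    with an n-channel window centered on c (zero-padded at the edges).
    """

    def __init__(self, window: int, k: float, alpha: float, beta: float):
        self.n, self.k, self.alpha, self.beta = window, k, alpha, beta

    def _denom(self, x: np.ndarray) -> np.ndarray:
        ssum = correlate1d(x * x, np.ones(self.n, dtype=np.float32), axis=3, mode="constant")
        return self.k + (self.alpha / self.n) * ssum

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        self._d = self._denom(x)
        return x * self._d ** (-self.beta)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, d, beta = self._x, self._d, self.beta
        inner = correlate1d(
            dout * x * d ** (-beta - 1.0),
            np.ones(self.n, dtype=np.float32),
            axis=3,
            mode="constant",
        )
        return dout * d ** (-beta) - (2.0 * self.alpha * beta / self.n) * x * inner


class _MaxPool2:
    def forward(self, x: np.ndarray) -> np.ndarray:
        bsz, h, w, c = x.shape
        xr = x.reshape(bsz, h // 2, 2, w // 2, 2, c)
        out = xr.max(axis=(2, 4))
        self._xr, self._out = xr, out
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        mask = self._xr == self._out[:, :, None, :, None, :]
        counts = mask.sum(axis=(2, 4), keepdims=True)
        dxr = mask * (dout[:, :, None, :, None, :] / counts)
        bsz, h2, _, w2, _, c = dxr.shape
        return dxr.reshape(bsz, h2 * 2, w2 * 2, c)


class _Dropout:
    def __init__(self, rate: float):
        self.rate = rate

    def forward(self, x: np.ndarray, *, train: bool, rng: np.random.Generator) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return (x * self._mask).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else (dout * self._mask).astype(np.float32)


class _Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out)).astype(np.float32)
        self.b = np.zeros(d_out, dtype=np.float32)
        self.vW = np.zeros_like(self.W)
        self.vb = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T

    def step(self, lr: float, mu: float) -> None:
        self.vW = mu * self.vW - lr * self.dW
        self.vb = mu * self.vb - lr * self.db
        self.W += self.vW
        self.b += self.vb


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class SensorCNN:
    """The 15-layer network: 3x(conv, ReLU[, LRN], pool), dropout, FC, softmax."""

    LAYER_NAMES = (
        "conv1", "relu1", "crossnorm1", "maxpool1",
        "conv2", "relu2", "crossnorm2", "maxpool2",
        "conv3", "relu3", "maxpool3",
        "dropout", "fully_connected", "softmax", "classification",
    )

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        h, w, c_in = config.input_shape
        f1, f2, f3 = config.conv_filters
        k1, k2, k3 = config.conv_kernels
        self.conv1 = _Conv2D(k1, c_in, f1, rng)
        self.relu1 = _ReLU()
        self.lrn1 = _LRN(config.lrn_window, config.lrn_k, config.lrn_alpha, config.lrn_beta)
        self.pool1 = _MaxPool2()
        self.conv2 = _Conv2D(k2, f1, f2, rng)
        self.relu2 = _ReLU()
        self.lrn2 = _LRN(config.lrn_window, config.lrn_k, config.lrn_alpha, config.lrn_beta)
        self.pool2 = _MaxPool2()
        self.conv3 = _Conv2D(k3, f2, f3, rng)
        self.relu3 = _ReLU()
        self.pool3 = _MaxPool2()
        self.dropout = _Dropout(config.dropout_rate)
        self.fc = _Dense((h // 8) * (w // 8) * f3, config.n_classes, rng)
        self._rng = rng

    @property
    def n_layers(self) -> int:
        return len(self.LAYER_NAMES)

    def architecture_summary(self) -> list[str]:
        return list(self.LAYER_NAMES)

    def forward(self, x: np.ndarray, *, train: bool = False) -> np.ndarray:
        """Class probabilities for a batch of images scaled to [0, 1]."""
        a = self.conv1.forward(x)
        a = self.pool1.forward(self.lrn1.forward(self.relu1.forward(a)))
        a = self.conv2.forward(a)
        a = self.pool2.forward(self.lrn2.forward(self.relu2.forward(a)))
        a = self.pool3.forward(self.relu3.forward(self.conv3.forward(a)))
        self._pool3_shape = a.shape
        a = a.reshape(a.shape[0], -1)
        a = self.dropout.forward(a, train=train, rng=self._rng)
        logits = self.fc.forward(a)
        self._probs = _softmax(logits)
        return self._probs

    def backward(self, y: np.ndarray, sample_weights: np.ndarray) -> None:
        n_cls = self.config.n_classes
        onehot = np.eye(n_cls, dtype=np.float32)[y]
        wsum = sample_weights.sum()
        dlogits = (self._probs - onehot) * (sample_weights[:, None] / wsum)
        d = self.fc.backward(dlogits.astype(np.float32))
        d = self.dropout.backward(d)
        d = d.reshape(self._pool3_shape)
        d = self.conv3.backward(self.relu3.backward(self.pool3.backward(d)))
        d = self.pool2.backward(d)
        d = self.conv2.backward(self.relu2.backward(self.lrn2.backward(d)))
        d = self.pool1.backward(d)
        self.conv1.backward(self.relu1.backward(self.lrn1.backward(d)))

    def step(self) -> None:
        lr, mu = self.config.learning_rate, self.config.momentum
        for layer in (self.conv1, self.conv2, self.conv3, self.fc):
            layer.step(lr, mu)

    def parameters(self) -> dict[str, np.ndarray]:
        out = {}
        for name, layer in (("conv1", self.conv1), ("conv2", self.conv2),
                            ("conv3", self.conv3), ("fc", self.fc)):
            out[f"{name}_W"] = layer.W
            out[f"{name}_b"] = layer.b
        return out


@dataclass
class TrainedSensorModel:
    network: SensorCNN
    config: ModelConfig
    training_log: list[float]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path, **self.network.parameters())
        sidecar = path.with_suffix(".json")
        sidecar.write_text(
            json.dumps({"config": asdict(self.config), "training_log": self.training_log},
                       indent=2)
        )

    @classmethod
    def load(cls, path: str | Path) -> "TrainedSensorModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        cfg = meta["config"]
        for key in ("input_shape", "conv_filters", "conv_kernels"):
            cfg[key] = tuple(cfg[key])
        config = ModelConfig(**cfg)
        net = SensorCNN(config)
        weights = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
        for name, layer in (("conv1", net.conv1), ("conv2", net.conv2),
                            ("conv3", net.conv3), ("fc", net.fc)):
            layer.W = weights[f"{name}_W"]
            layer.b = weights[f"{name}_b"]
        return cls(network=net, config=config, training_log=meta["training_log"])


def build_cnn(config: ModelConfig | None = None) -> SensorCNN:
    """Construct the untrained 15-layer network."""
    return SensorCNN(config or ModelConfig())


def _as_image_array(scalograms) -> np.ndarray:
    """Stack ScalogramImage objects or raw arrays into (N, H, W, 1) float32 in [0, 1]."""
    arrs = []
    for s in scalograms:
        p = s.pixels if hasattr(s, "pixels") else np.asarray(s)
        if p.ndim == 2:
            p = p[:, :, None]
        arrs.append(p)
    x = np.stack(arrs).astype(np.float32)
    if x.max() > 1.0:
        x /= 255.0
    return x


def train_sensor_model(
    scalograms: Sequence,
    labels: Sequence[int],
    config: ModelConfig | None = None,
) -> TrainedSensorModel:
    """Train the CNN on labeled scalograms (8 epochs, batch 32 by default).

    Class imbalance is handled by inverse-frequency sample weighting.
    Deterministic under a fixed config.seed (single-threaded execution).
    """
    config = config or ModelConfig()
    y = np.asarray(labels, dtype=int)
    if len(scalograms) == 0:
        raise ValueError("empty training set")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels must contain both classes")
    x = _as_image_array(scalograms)
    if x.shape[1:] != tuple(config.input_shape):
        raise ValueError(f"image shape {x.shape[1:]} != {config.input_shape}")

    counts = np.bincount(y, minlength=config.n_classes).astype(float)
    class_w = len(y) / (np.count_nonzero(counts) * np.maximum(counts, 1.0))
    weights = class_w[y].astype(np.float32)

    net = SensorCNN(config)
    shuffle_rng = np.random.default_rng(config.seed + 1)
    log: list[float] = []
    for _epoch in range(config.epochs):
        order = shuffle_rng.permutation(len(y))
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(y), config.batch_size):
            idx = order[start : start + config.batch_size]
            probs = net.forward(x[idx], train=True)
            w = weights[idx]
            loss = float(
                -(w * np.log(probs[np.arange(len(idx)), y[idx]] + 1e-12)).sum() / w.sum()
            )
            net.backward(y[idx], w)
            net.step()
            epoch_loss += loss
            n_batches += 1
        log.append(epoch_loss / n_batches)
    return TrainedSensorModel(network=net, config=config, training_log=log)


def predict_proba(model: TrainedSensorModel, scalograms: Sequence) -> np.ndarray:
    """Class probability pairs (non-intake, intake) for a batch of scalograms."""
    x = _as_image_array(scalograms)
    if x.shape[1:] != tuple(model.config.input_shape):
        raise ValueError(f"image shape {x.shape[1:]} != {model.config.input_shape}")
    out = []
    bsz = model.config.batch_size
    for start in range(0, len(x), bsz):
        out.append(model.network.forward(x[start : start + bsz], train=False))
    return np.concatenate(out)


def predict_intake(model: TrainedSensorModel, scalogram) -> float:
    """Sensor confidence score Ss: softmax probability of the intake class."""
    return float(predict_proba(model, [scalogram])[0, 1])
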
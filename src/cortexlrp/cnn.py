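"""A small VGG-style binary classifier, implemented directly on NumPy.

Architecture (for a 60x120 single-channel input): two 3x3 valid-padding
convolutions + one 2x2 max pool, repeated twice (channel plan c1, c2=128),
then flatten and three fully connected layers (ReLU + 50% dropout on the
first two, sigmoid output).  With valid padding the spatial trace is
60x120 -> 58x118 -> 56x116 -> 28x58 -> 26x56 -> 24x54 -> 12x27, so the
flattened dimension is 128*12*27 = 41,472.

Training minimizes binary cross-entropy with Adam and early-stops when the
validation accuracy has not improved for ``patience`` epochs, restoring the
best-validation weights.  Every layer caches its forward inputs (and max-pool
argmax switches) in evaluation mode, which is what the relevance-propagation
module consumes.

The implementation is deliberately self-contained: convolutions run through
im2col/col2im so that forward, backprop, and relevance propagation all share
one linear-map representation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import h5py
import numpy as np

__all__ = [
    "TrainConfig",
    "CNNModel",
    "Conv2D",
    "MaxPool2D",
    "Flatten",
    "Dense",
    "build_model",
    "train",
    "grid_search_lr",
    "binary_cross_entropy",
    "save_model",
    "load_model",
]


@dataclass
class TrainConfig:
    """Optimization settings.

    ``patience`` implements "validation accuracy did not improve for N
    epochs"; ``validation_fraction`` is the share of the training data held
    out for early stopping (1/11 by default).
    """

    lr_grid: tuple[float, ...] = (1e-4, 1e-3)
    patience: int = 20
    max_epochs: int = 300
    batch_size: int = 64
    validation_fraction: float = 1.0 / 11.0
    seed: int = 0

    def validate(self) -> None:
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if not self.lr_grid:
            raise ValueError("learning-rate grid must be non-empty")
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation_fraction must be in (0, 1)")


# ---------------------------------------------------------------------------
# im2col machinery shared by forward, backward, and LRP


def im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, H, W) -> (N, P, C*k*k) patches for a valid k x k convolution."""
    sw = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    n, c, ho, wo = sw.shape[:4]
    return np.ascontiguousarray(sw.transpose(0, 2, 3, 1, 4, 5)).reshape(n, ho * wo, c * k * k)


def col2im(gcols: np.ndarray, x_shape: tuple, k: int) -> np.ndarray:
    """Adjoint of :func:`im2col`: scatter patch gradients back to the input."""
    n, c, h, w = x_shape
    ho, wo = h - k + 1, w - k + 1
    g = gcols.reshape(n, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    out = np.zeros(x_shape)
    for i in range(k):
        for j in range(k):
            out[:, :, i : i + ho, j : j + wo] += g[:, :, :, :, i, j]
    return out


class Conv2D:
    """3x3 (configurable) valid-padding convolution with ReLU."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int, rng: np.random.Generator):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        fan_in = in_channels * kernel * kernel
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, out_channels))
        self.b = np.zeros(out_channels)
        self.grads: dict[str, np.ndarray] = {}
        self.cache: dict[str, np.ndarray] = {}

    @property
    def params(self) -> dict[str, np.ndarray]:
        return {"W": self.W, "b": self.b}

    def out_shape(self, shape: tuple) -> tuple:
        c, h, w = shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {c}")
        ho, wo = h - self.kernel + 1, w - self.kernel + 1
        if ho < 1 or wo < 1:
            raise ValueError(f"input {h}x{w} too small for a valid {self.kernel}x{self.kernel} conv")
        return (self.out_channels, ho, wo)

    def forward(self, x: np.ndarray, train: bool, rng=None) -> np.ndarray:
        n, c, h, w = x.shape
        _, ho, wo = self.out_shape((c, h, w))
        cols = im2col(x, self.kernel)
        z = cols @ self.W + self.b
        out = np.maximum(z, 0.0)
        self.cache = {"x_shape": x.shape, "input": x, "cols": cols, "z": z}
        return out.reshape(n, ho, wo, self.out_channels).transpose(0, 3, 1, 2)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        n, f, ho, wo = gout.shape
        g = gout.transpose(0, 2, 3, 1).reshape(n, ho * wo, f)
        gz = g * (self.cache["z"] > 0)
        self.grads["W"] = np.einsum("npk,npf->kf", self.cache["cols"], gz)
        self.grads["b"] = gz.sum(axis=(0, 1))
        return col2im(gz @ self.W.T, self.cache["x_shape"], self.kernel)


class MaxPool2D:
    """2x2, stride-2 max pooling; odd trailing rows/columns are dropped.

    Argmax switches are recorded in row-major window order (ties go to the
    first position), for backprop and winner-take-all relevance routing.
    """

    params: dict = {}

    def __init__(self, size: int = 2):
        self.size = size
        self.grads: dict = {}
        self.cache: dict[str, np.ndarray] = {}

    def out_shape(self, shape: tuple) -> tuple:
        c, h, w = shape
        return (c, h // self.size, w // self.size)

    def _windows(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        s = self.size
        ho, wo = h // s, w // s
        xc = x[:, :, : ho * s, : wo * s]
        return xc.reshape(n, c, ho, s, wo, s).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, ho, wo, s * s
        )

    def forward(self, x: np.ndarray, train: bool, rng=None) -> np.ndarray:
        win = self._windows(x)
        switches = win.argmax(axis=-1)
        self.cache = {"x_shape": x.shape, "input": x, "switches": switches}
        return np.take_along_axis(win, switches[..., None], axis=-1)[..., 0]

    def unpool(self, values: np.ndarray) -> np.ndarray:
        """Scatter per-window values back to the winning input positions."""
        if not self.cache:
            raise ValueError("no pooling switches recorded; run forward first")
        n, c, h, w = self.cache["x_shape"]
        s = self.size
        sw = self.cache["switches"]
        n_, c_, ho, wo = sw.shape
        out = np.zeros((n, c, ho, wo, s * s))
        np.put_along_axis(out, sw[..., None], values[..., None], axis=-1)
        out = out.reshape(n, c, ho, wo, s, s).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, ho * s, wo * s
        )
        full = np.zeros((n, c, h, w))
        full[:, :, : ho * s, : wo * s] = out
        return full

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return self.unpool(gout)


class Flatten:
    params: dict = {}

    def __init__(self):
        self.grads: dict = {}
        self.cache: dict = {}

    def out_shape(self, shape: tuple) -> tuple:
        return (int(np.prod(shape)),)

    def forward(self, x: np.ndarray, train: bool, rng=None) -> np.ndarray:
        self.cache = {"x_shape": x.shape, "input": x}
        return x.reshape(x.shape[0], -1)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout.reshape(self.cache["x_shape"])


class Dense:
    """Fully connected layer with optional ReLU/sigmoid and inverted dropout."""

    def __init__(
        self,
        in_features: int,
        out_features: int,
        activation: str | None,
        dropout: float,
        rng: np.random.Generator,
    ):
        if activation not in (None, "relu", "sigmoid"):
            raise ValueError(f"unknown activation {activation!r}")
        self.in_features = in_features
        self.out_features = out_features
        self.activation = activation
        self.dropout = dropout
        scale = np.sqrt(2.0 / in_features) if activation == "relu" else np.sqrt(1.0 / in_features)
        self.W = rng.normal(0.0, scale, size=(in_features, out_features))
        self.b = np.zeros(out_features)
        self.grads: dict[str, np.ndarray] = {}
        self.cache: dict[str, np.ndarray] = {}

    @property
    def params(self) -> dict[str, np.ndarray]:
        return {"W": self.W, "b": self.b}

    def out_shape(self, shape: tuple) -> tuple:
        if shape != (self.in_features,):
            raise ValueError(f"expected input shape ({self.in_features},), got {shape}")
        return (self.out_features,)

    def forward(self, x: np.ndarray, train: bool, rng=None) -> np.ndarray:
        z = x @ self.W + self.b
        if self.activation == "relu":
            a = np.maximum(z, 0.0)
        elif self.activation == "sigmoid":
            a = 1.0 / (1.0 + np.exp(-z))
        else:
            a = z
        mask = None
        if train and self.dropout > 0:
            if rng is None:
                raise ValueError("training-mode forward with dropout requires an rng")
            mask = (rng.random(a.shape) >= self.dropout) / (1.0 - self.dropout)
            a = a * mask
        self.cache = {"input": x, "z": z, "mask": mask}
        return a

    def backward(self, gout: np.ndarray, from_preactivation: bool = False) -> np.ndarray:
        if self.cache.get("mask") is not None:
            gout = gout * self.cache["mask"]
        z = self.cache["z"]
        if from_preactivation or self.activation is None:
            gz = gout
        elif self.activation == "relu":
            gz = gout * (z > 0)
        else:  # sigmoid
            p = 1.0 / (1.0 + np.exp(-z))
            gz = gout * p * (1.0 - p)
        self.grads["W"] = self.cache["input"].T @ gz
        self.grads["b"] = gz.sum(axis=0)
        return gz @ self.W.T


class CNNModel:
    """An ordered layer stack with shared forward/training/LRP plumbing."""

    def __init__(self, layers: list, input_shape: tuple[int, int]):
        self.layers = layers
        self.input_shape = input_shape  # (H, W), single channel

    def shape_trace(self) -> list[tuple[str, tuple]]:
        """Per-layer output shapes from the configured input; raises on underflow."""
        shape = (1, *self.input_shape)
        trace = [("input", shape)]
        for layer in self.layers:
            shape = layer.out_shape(shape)
            trace.append((type(layer).__name__, shape))
        return trace

    def _as_batch(self, images: np.ndarray) -> np.ndarray:
        images = np.asarray(images, dtype=np.float64)
        if images.ndim == 2:
            images = images[None]
        if images.shape[-2:] != self.input_shape:
            raise ValueError(f"expected {self.input_shape} images, got {images.shape[-2:]}")
        return images[:, None, :, :]  # add channel axis

    def forward(self, images: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        """Probabilities in (0, 1), one per image.

        Evaluation mode (train=False) disables dropout and is a pure function
        of (weights, input); layer caches are left populated for LRP.
        """
        x = self._as_batch(images)
        for layer in self.layers:
            x = layer.forward(x, train, rng)
        return x[:, 0]

    def logits(self) -> np.ndarray:
        """Pre-sigmoid scores cached by the most recent forward pass."""
        return self.layers[-1].cache["z"][:, 0]

    def backward_from_logits(self, dlogit: np.ndarray) -> None:
        """Backprop a gradient w.r.t. the final pre-activation."""
        g = self.layers[-1].backward(dlogit[:, None], from_preactivation=True)
        for layer in reversed(self.layers[:-1]):
            g = layer.backward(g)

    def get_weights(self) -> list[dict[str, np.ndarray]]:
        return [{k: v.copy() for k, v in layer.params.items()} for layer in self.layers]

    def set_weights(self, weights: list[dict[str, np.ndarray]]) -> None:
        for layer, w in zip(self.layers, weights):
            for k, v in w.items():
                layer.params[k][...] = v

    def trainable(self) -> list:
        return [layer for layer in self.layers if layer.params]


def build_model(
    input_shape: tuple[int, int] = (60, 120),
    channel_plan: tuple[int, int] = (64, 128),
    dense_plan: tuple[int, int] = (256, 64),
    seed: int = 0,
) -> CNNModel:
    """Construct the two-block conv stack + three dense layers.

    Raises if the input is too small for the valid-padding convolutions.
    The returned model's ``shape_trace`` reports every intermediate shape.
    """
    rng = np.random.default_rng(seed)
    c1, c2 = channel_plan
    h1, h2 = dense_plan
    layers: list = [
        Conv2D(1, c1, 3, rng),
        Conv2D(c1, c1, 3, rng),
        MaxPool2D(2),
        Conv2D(c1, c2, 3, rng),
        Conv2D(c2, c2, 3, rng),
        MaxPool2D(2),
        Flatten(),
    ]
    # compute the flattened size, validating spatial arithmetic on the way
    shape = (1, *input_shape)
    for layer in layers:
        shape = layer.out_shape(shape)
    flat = shape[0]
    layers += [
        Dense(flat, h1, "relu", 0.5, rng),
        Dense(h1, h2, "relu", 0.5, rng),
        Dense(h2, 1, "sigmoid", 0.0, rng),
    ]
    model = CNNModel(layers, tuple(input_shape))
    model.shape_trace()  # raises on underflow
    return model


def binary_cross_entropy(p: np.ndarray, y: np.ndarray, eps: float = 1e-12) -> float:
    p = np.clip(p, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


class _Adam:
    def __init__(self, layers, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.layers = layers
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in layers]
        self.t = 0

    def step(self):
        self.t += 1
        for layer, m, v in zip(self.layers, self.m, self.v):
            for k, p in layer.params.items():
                g = layer.grads[k]
                m[k] = self.b1 * m[k] + (1 - self.b1) * g
                v[k] = self.b2 * v[k] + (1 - self.b2) * g * g
                mhat = m[k] / (1 - self.b1**self.t)
                vhat = v[k] / (1 - self.b2**self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _accuracy(model: CNNModel, X: np.ndarray, y: np.ndarray, batch: int = 256) -> float:
    correct = 0
    for i in range(0, len(X), batch):
        p = model.forward(X[i : i + batch])
        correct += int(np.sum((p >= 0.5).astype(int) == y[i : i + batch]))
    return correct / len(X)


def train(
    model: CNNModel,
    train_set: tuple[np.ndarray, np.ndarray],
    val_set: tuple[np.ndarray, np.ndarray],
    lr: float,
    config: TrainConfig,
) -> tuple[CNNModel, dict]:
    """Adam / binary cross-entropy training with early stopping.

    Stops once validation accuracy has not improved for ``config.patience``
    epochs (or at ``max_epochs``) and restores the best-validation weights.
    Returns the model and a history dict with per-epoch train loss and
    validation accuracy.
    """
    config.validate()
    X_tr, y_tr = train_set
    X_va, y_va = val_set
    if len(X_tr) == 0 or len(X_va) == 0:
        raise ValueError("empty training or validation set")
    y_tr = np.asarray(y_tr, dtype=np.float64)
    y_va = np.asarray(y_va, dtype=np.float64)

    rng = np.random.default_rng(config.seed)
    opt = _Adam(model.trainable(), lr)
    best_acc = -np.inf
    best_weights = model.get_weights()
    since_best = 0
    history: dict[str, list] = {"train_loss": [], "val_accuracy": []}

    for _epoch in range(config.max_epochs):
        order = rng.permutation(len(X_tr))
        losses = []
        for i in range(0, len(order), config.batch_size):
            idx = order[i : i + config.batch_size]
            xb, yb = X_tr[idx], y_tr[idx]
            p = model.forward(xb, train=True, rng=rng)
            losses.append(binary_cross_entropy(p, yb))
            model.backward_from_logits((p - yb) / len(yb))
            opt.step()
        val_acc = _accuracy(model, X_va, y_va)
        history["train_loss"].append(float(np.mean(losses)))
        history["val_accuracy"].append(val_acc)
        if val_acc > best_acc:
            best_acc = val_acc
            best_weights = model.get_weights()
            since_best = 0
        else:
            since_best += 1
        if since_best > config.patience:
            break

    model.set_weights(best_weights)
    history["best_val_accuracy"] = float(best_acc)
    return model, history


def grid_search_lr(
    model_builder,
    train_set: tuple[np.ndarray, np.ndarray],
    val_set: tuple[np.ndarray, np.ndarray],
    config: TrainConfig,
) -> float:
    """Pick the learning rate with the best validation accuracy.

    One model per grid value is trained on the same train/validation split
    (``model_builder() -> CNNModel`` must rebuild identically-initialized
    models).  Ties are broken toward the smaller rate.
    """
    config.validate()
    best = (-np.inf, np.inf)  # (accuracy, -(-lr)) handled explicitly below
    best_lr = None
    for lr in sorted(config.lr_grid):
        model = model_builder()
        _, history = train(model, train_set, val_set, lr, config)
        acc = history["best_val_accuracy"]
        if acc > best[0]:  # strict: earlier (smaller) lr wins ties
            best = (acc, lr)
            best_lr = lr
    return best_lr


# ---------------------------------------------------------------------------
# serialization: weights + a JSON architecture descriptor in one HDF5 file


def _describe(model: CNNModel) -> dict:
    spec = []
    for layer in model.layers:
        if isinstance(layer, Conv2D):
            spec.append(
                {"type": "conv", "in": layer.in_channels, "out": layer.out_channels,
                 "kernel": layer.kernel}
            )
        elif isinstance(layer, MaxPool2D):
            spec.append({"type": "pool", "size": layer.size})
        elif isinstance(layer, Flatten):
            spec.append({"type": "flatten"})
        elif isinstance(layer, Dense):
            spec.append(
                {"type": "dense", "in": layer.in_features, "out": layer.out_features,
                 "activation": layer.activation, "dropout": layer.dropout}
            )
        else:  # pragma: no cover
            raise TypeError(f"unknown layer {type(layer).__name__}")
    return {"input_shape": list(model.input_shape), "layers": spec}


def save_model(model: CNNModel, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["architecture"] = json.dumps(_describe(model))
        for i, layer in enumerate(model.layers):
            for k, v in layer.params.items():
                f.create_dataset(f"layer{i}/{k}", data=v)


def load_model(path) -> CNNModel:
    rng = np.random.default_rng(0)
    with h5py.File(path, "r") as f:
        arch = json.loads(f.attrs["architecture"])
        layers: list = []
        for i, spec in enumerate(arch["layers"]):
            if spec["type"] == "conv":
                layer = Conv2D(spec["in"], spec["out"], spec["kernel"], rng)
            elif spec["type"] == "pool":
                layer = MaxPool2D(spec["size"])
            elif spec["type"] == "flatten":
                layer = Flatten()
            else:
                layer = Dense(spec["in"], spec["out"], spec["activation"], spec["dropout"], rng)
            for k in layer.params:
                layer.params[k][...] = f[f"layer{i}/{k}"][...]
            layers.append(layer)
    return CNNModel(layers, tuple(arch["input_shape"]))
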
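"""Compact CNN classifiers implemented directly on numpy.

Three architectures are provided:

* ``shallow`` — a single 5x5 convolution stage (8 filters) + pool + ReLU,
  then a fully connected softmax head;
* ``lenet5`` — the classic three-stage LeNet-5 form: 5x5 convolutions with
  6/16/120 filters and an 84-unit dense layer before the head;
* ``tri_ccnn`` — three convolutions with shrinking kernels 5x5 -> 3x3 ->
  2x2 and filter counts 8/8/4, max-pool + ReLU after each convolution and
  batch normalization after the second convolution.

Training follows a fixed regime: SGD with momentum (0.9), learning rate
1e-4, mini-batches of 4, 10 epochs, cross-entropy loss, no early stopping,
no learning-rate schedule, no weight decay.  All randomness (weight
initialization, epoch shuffling) flows from explicit seeds, so a run is
bit-reproducible on one device.

The layer stack is introspectable via ``Model.layer_summary`` so tests can
assert the exact conv/pool/ReLU ordering and kernel/filter counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ConfigurationError, ValidationError

ARCH_NAMES = ("shallow", "lenet5", "tri_ccnn")


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Layer:
    """Base layer: forward/backward plus parameter introspection."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def describe(self) -> dict:
        return {"type": type(self).__name__}


class Conv2d(Layer):
    """Valid (no padding) convolution, stride 1, via im2col + matmul."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        fan_in = in_channels * kernel * kernel
        # He initialization (fan-in scaled), standard for ReLU stacks
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(out_channels, fan_in)).astype(np.float32)
        b = np.zeros(out_channels, dtype=np.float32)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, C, H, W = x.shape
        k = self.kernel
        if C != self.in_channels:
            raise ConfigurationError(
                f"conv expected {self.in_channels} channels, got {C}")
        if H < k or W < k:
            raise ConfigurationError("input smaller than the conv kernel")
        win = sliding_window_view(x, (k, k), axis=(2, 3))  # (B,C,Ho,Wo,k,k)
        Ho, Wo = win.shape[2], win.shape[3]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B, Ho * Wo, C * k * k)
        self._cols = cols.astype(np.float32)
        self._in_shape = x.shape
        out = self._cols @ self.params[0].T + self.params[1]
        return out.reshape(B, Ho, Wo, self.out_channels).transpose(0, 3, 1, 2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        B, O, Ho, Wo = grad.shape
        k = self.kernel
        g2 = grad.transpose(0, 2, 3, 1).reshape(B, Ho * Wo, O)
        self.grads[0][...] = np.einsum("bno,bni->oi", g2, self._cols)
        self.grads[1][...] = g2.sum(axis=(0, 1))
        dcols = g2 @ self.params[0]                     # (B, Ho*Wo, C*k*k)
        dcols = dcols.reshape(B, Ho, Wo, self.in_channels, k, k)
        dx = np.zeros(self._in_shape, dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dx[:, :, i:i + Ho, j:j + Wo] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return dx

    def describe(self) -> dict:
        return {"type": "Conv2d", "kernel": self.kernel,
                "filters": self.out_channels}


class MaxPool2d(Layer):
    """2x2 max pooling with stride 2 (stride = pool size); odd edges dropped."""

    def __init__(self, pool: int = 2) -> None:
        super().__init__()
        self.pool = pool

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        p = self.pool
        B, C, H, W = x.shape
        Hp, Wp = H // p, W // p
        self._in_shape = x.shape
        xc = x[:, :, :Hp * p, :Wp * p]
        xw = xc.reshape(B, C, Hp, p, Wp, p).transpose(0, 1, 2, 4, 3, 5)
        xw = xw.reshape(B, C, Hp, Wp, p * p)
        self._argmax = xw.argmax(axis=-1)
        return np.take_along_axis(xw, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        p = self.pool
        B, C, Hp, Wp = grad.shape
        gw = np.zeros((B, C, Hp, Wp, p * p), dtype=np.float32)
        np.put_along_axis(gw, self._argmax[..., None], grad[..., None], axis=-1)
        gw = gw.reshape(B, C, Hp, Wp, p, p).transpose(0, 1, 2, 4, 3, 5)
        gw = gw.reshape(B, C, Hp * p, Wp * p)
        dx = np.zeros(self._in_shape, dtype=np.float32)
        dx[:, :, :Hp * p, :Wp * p] = gw
        return dx

    def describe(self) -> dict:
        return {"type": "MaxPool2d", "pool": self.pool, "stride": self.pool}


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, 0.0).astype(np.float32)

    def describe(self) -> dict:
        return {"type": "ReLU"}


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics for eval."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1) -> None:
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        gamma = np.ones(channels, dtype=np.float32)
        beta = np.zeros(channels, dtype=np.float32)
        self.params = [gamma, beta]
        self.grads = [np.zeros_like(gamma), np.zeros_like(beta)]
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._xhat = xhat.astype(np.float32)
        self._inv_std = inv_std.astype(np.float32)
        return (self.params[0][None, :, None, None] * self._xhat
                + self.params[1][None, :, None, None])

    def backward(self, grad: np.ndarray) -> np.ndarray:
        B, C, H, W = grad.shape
        n = B * H * W
        axes = (0, 2, 3)
        self.grads[0][...] = (grad * self._xhat).sum(axis=axes)
        self.grads[1][...] = grad.sum(axis=axes)
        dxhat = grad * self.params[0][None, :, None, None]
        s1 = dxhat.sum(axis=axes, keepdims=True)
        s2 = (dxhat * self._xhat).sum(axis=axes, keepdims=True)
        dx = (self._inv_std[None, :, None, None] / n) * (
            n * dxhat - s1 - self._xhat * s2
        )
        return dx.astype(np.float32)

    def describe(self) -> dict:
        return {"type": "BatchNorm2d"}


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._in_shape)

    def describe(self) -> dict:
        return {"type": "Flatten"}


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        w = rng.normal(0.0, np.sqrt(2.0 / in_features),
                       size=(in_features, out_features)).astype(np.float32)
        b = np.zeros(out_features, dtype=np.float32)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x.astype(np.float32)
        return x @ self.params[0] + self.params[1]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return (grad @ self.params[0].T).astype(np.float32)

    def describe(self) -> dict:
        return {"type": "Dense", "units": self.out_features}


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(probs[np.arange(len(y)), y], 1e-12, None)
    return float(-np.mean(np.log(p)))


# ---------------------------------------------------------------------------
# architectures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArchitectureSpec:
    """Declarative description of one of the three classifier families."""

    name: str
    input_shape: tuple[int, int, int] = (451, 451, 3)   # H, W, C
    n_classes: int = 2

    def __post_init__(self) -> None:
        if self.name not in ARCH_NAMES:
            raise ConfigurationError(f"unknown architecture {self.name!r}")
        if self.n_classes < 2:
            raise ConfigurationError("need at least two classes")


class Model:
    """A sequential layer stack with a softmax classification head."""

    def __init__(self, spec: ArchitectureSpec, layers: list[Layer]) -> None:
        self.spec = spec
        self.layers = layers

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a (B, C, H, W) float batch."""
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def predict_proba(self, x: np.ndarray, batch_size: int = 16) -> np.ndarray:
        """Class probabilities (rows sum to 1) in eval mode."""
        chunks = [softmax(self.forward(x[i:i + batch_size], train=False))
                  for i in range(0, len(x), batch_size)]
        return np.concatenate(chunks) if chunks else np.zeros((0, self.spec.n_classes))

    # -- introspection ------------------------------------------------------

    def layer_summary(self) -> list[dict]:
        return [layer.describe() for layer in self.layers]

    @property
    def conv_kernel_sizes(self) -> list[int]:
        return [d["kernel"] for d in self.layer_summary() if d["type"] == "Conv2d"]

    @property
    def conv_filter_counts(self) -> list[int]:
        return [d["filters"] for d in self.layer_summary() if d["type"] == "Conv2d"]

    def parameters(self):
        for layer in self.layers:
            yield from zip(layer.params, layer.grads)

    def state_arrays(self) -> list[np.ndarray]:
        arrays = []
        for layer in self.layers:
            arrays.extend(layer.params)
            if isinstance(layer, BatchNorm2d):
                arrays.extend([layer.running_mean, layer.running_var])
        return arrays

    def set_state_arrays(self, arrays: Sequence[np.ndarray]) -> None:
        it = iter(arrays)
        for layer in self.layers:
            for i in range(len(layer.params)):
                layer.params[i][...] = next(it)
            if isinstance(layer, BatchNorm2d):
                layer.running_mean[...] = next(it)
                layer.running_var[...] = next(it)


def _head_size(layers: list[Layer], input_shape: tuple[int, int, int]) -> int:
    """Dry-run the convolutional trunk to size the first dense layer."""
    h, w, c = input_shape
    x = np.zeros((1, c, h, w), dtype=np.float32)
    try:
        for layer in layers:
            x = layer.forward(x, train=False)
    except ConfigurationError:
        return 0
    return int(np.prod(x.shape[1:]))


def build_model(
    spec: ArchitectureSpec | str,
    input_shape: tuple[int, int, int] | None = None,
    seed: int = 0,
) -> Model:
    """Instantiate an untrained classifier for ``spec``.

    ``input_shape`` (H, W, C) overrides the spec's; weights are drawn from
    a generator seeded with ``seed``.
    """
    if isinstance(spec, str):
        spec = ArchitectureSpec(name=spec)
    if input_shape is not None:
        spec = ArchitectureSpec(spec.name, tuple(input_shape), spec.n_classes)
    rng = np.random.default_rng(seed)
    c_in = spec.input_shape[2]

    if spec.name == "shallow":
        trunk: list[Layer] = [
            Conv2d(c_in, 8, 5, rng), MaxPool2d(), ReLU(),
        ]
    elif spec.name == "lenet5":
        trunk = [
            Conv2d(c_in, 6, 5, rng), MaxPool2d(), ReLU(),
            Conv2d(6, 16, 5, rng), MaxPool2d(), ReLU(),
            Conv2d(16, 120, 5, rng), ReLU(),
        ]
    else:  # tri_ccnn
        trunk = [
            Conv2d(c_in, 8, 5, rng), MaxPool2d(), ReLU(),
            Conv2d(8, 8, 3, rng), BatchNorm2d(8), MaxPool2d(), ReLU(),
            Conv2d(8, 4, 2, rng), MaxPool2d(), ReLU(),
        ]

    n_flat = _head_size(trunk, spec.input_shape)
    if n_flat == 0:
        raise ConfigurationError(
            f"input {spec.input_shape[:2]} collapses to zero features in the "
            f"{spec.name} trunk; use a larger input grid")
    layers = trunk + [Flatten()]
    if spec.name == "lenet5":
        layers += [Dense(n_flat, 84, rng), ReLU(),
                   Dense(84, spec.n_classes, rng)]
    else:
        layers += [Dense(n_flat, spec.n_classes, rng)]
    return Model(spec, layers)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainingConfig:
    """Fixed training regime: SGDM, lr 1e-4, batch 4, 10 epochs, CE loss."""

    learning_rate: float = 1e-4
    momentum: float = 0.9
    batch_size: int = 4
    epochs: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 0:
            raise ConfigurationError("invalid training configuration")


@dataclass
class TrainedClassifier:
    """A trained model plus its config and per-epoch training history."""

    model: Model
    config: TrainingConfig
    history: list[dict] = field(default_factory=list)

    @property
    def input_shape(self) -> tuple[int, int, int]:
        return self.model.spec.input_shape


def images_to_array(images, input_shape: tuple[int, int, int] | None = None) -> np.ndarray:
    """Convert a LabeledDataset / uint8 image stack to a (B, C, H, W) float batch.

    Pixels are scaled to [0, 1].  If ``input_shape`` is given, geometry is
    validated against it.
    """
    if hasattr(images, "pixel_array"):
        stack = images.pixel_array()
    else:
        stack = np.asarray(images)
    if stack.ndim != 4 or stack.shape[-1] != 3:
        raise ConfigurationError("expected an (n, H, W, 3) image stack")
    if input_shape is not None and stack.shape[1:] != tuple(input_shape):
        raise ConfigurationError(
            f"image geometry {stack.shape[1:]} does not match model input "
            f"{tuple(input_shape)}")
    return (stack.astype(np.float32) / 255.0).transpose(0, 3, 1, 2)


def train(
    model: Model,
    dataset,
    config: TrainingConfig | None = None,
    labels: np.ndarray | None = None,
) -> TrainedClassifier:
    """Train ``model`` in place under the fixed regime.

    ``dataset`` is either a LabeledDataset or a (B, C, H, W) float array
    with ``labels`` supplied separately.  Exactly ``config.epochs`` passes
    are run (the last mini-batch may be smaller than 4); a fixed seed makes
    the run bit-reproducible.
    """
    config = config or TrainingConfig()
    if hasattr(dataset, "labels"):
        y = dataset.labels()
        x = images_to_array(dataset, model.spec.input_shape)
    else:
        x = np.asarray(dataset, dtype=np.float32)
        y = np.asarray(labels)
    if len(x) == 0:
        raise ValidationError("empty training set")
    if len(np.unique(y)) < 2:
        raise ValidationError("training set must contain both classes")

    rng = np.random.default_rng(config.seed)
    velocity = [np.zeros_like(p) for p, _ in model.parameters()]
    history: list[dict] = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(x))
        losses, correct = [], 0
        for start in range(0, len(x), config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb = x[idx], y[idx]
            logits = model.forward(xb, train=True)
            probs = softmax(logits)
            losses.append(cross_entropy(probs, yb) * len(idx))
            correct += int((probs.argmax(axis=1) == yb).sum())
            grad = probs.copy()
            grad[np.arange(len(yb)), yb] -= 1.0
            grad /= len(yb)
            model.backward(grad.astype(np.float32))
            for v, (p, g) in zip(velocity, model.parameters()):
                v *= config.momentum
                v -= config.learning_rate * g
                p += v
        history.append({
            "epoch": epoch + 1,
            "loss": float(np.sum(losses) / len(x)),
            "accuracy": correct / len(x),
        })
    return TrainedClassifier(model=model, config=config, history=history)


def predict(classifier: TrainedClassifier | Model, images):
    """Predicted labels and class probabilities.

    Argmax over the softmax output; ties break toward class index 0
    (numpy argmax returns the first maximal index).
    """
    model = classifier.model if isinstance(classifier, TrainedClassifier) else classifier
    x = images_to_array(images, model.spec.input_shape) \
        if not (isinstance(images, np.ndarray) and images.ndim == 4
                and images.shape[1] == model.spec.input_shape[2]) \
        else images
    probs = model.predict_proba(np.asarray(x, dtype=np.float32))
    return probs.argmax(axis=1), probs


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_classifier(clf: TrainedClassifier, path: str | Path) -> Path:
    path = Path(path)
    arrays = {f"arr_{i}": a for i, a in enumerate(clf.model.state_arrays())}
    meta = {
        "name": clf.model.spec.name,
        "input_shape": list(clf.model.spec.input_shape),
        "n_classes": clf.model.spec.n_classes,
        "config": {
            "learning_rate": clf.config.learning_rate,
            "momentum": clf.config.momentum,
            "batch_size": clf.config.batch_size,
            "epochs": clf.config.epochs,
            "seed": clf.config.seed,
        },
        "history": clf.history,
    }
    np.savez(path, meta=json.dumps(meta), **arrays)
    return path


def load_classifier(path: str | Path) -> TrainedClassifier:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        arrays = [data[f"arr_{i}"] for i in range(len(data.files) - 1)]
    spec = ArchitectureSpec(meta["name"], tuple(meta["input_shape"]), meta["n_classes"])
    model = build_model(spec, seed=0)
    model.set_state_arrays(arrays)
    return TrainedClassifier(model=model,
                             config=TrainingConfig(**meta["config"]),
                             history=meta["history"])
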
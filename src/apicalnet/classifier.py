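"""The two-class lesion CNN and its SGDM training recipe.

The network is an AlexNet-derived stack scaled to 200 x 100 x 3 tooth
crops: two convolution blocks (conv -> ReLU -> cross-channel LRN -> max
pool) followed by three fully-connected layers with dropout and a
softmax over {normal, lesion}.  Layer output shapes are asserted against
the canonical configuration at build time, so any kernel/stride/padding
edit that changes a shape fails loudly and names the layer.

Training is plain mini-batch stochastic gradient descent with momentum
0.9, initial learning rate 6e-5, L2 weight decay 1e-4, mini-batches of
128 and up to 100 epochs; optional global-L2-norm gradient clipping and
validation-loss patience.  Inputs are zero-centered by the training-set
mean image (stored with the model); grayscale crops are replicated to
three channels at the input.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from . import _layers as L
from .dataset import LABELS, LabeledDataset

INPUT_SHAPE = (200, 100, 3)  # height, width, channels


class NetworkBuildError(ValueError):
    """A realized layer shape deviates from its declared LayerSpec."""


@dataclass(frozen=True)
class LayerSpec:
    """One row of the architecture table: kind, declared output shape, params."""

    name: str
    out_shape: tuple[int, ...]
    params: dict = field(default_factory=dict)


@dataclass(frozen=True)
class NetworkConfig:
    layers: tuple[LayerSpec, ...]
    n_classes: int = 2

    def __post_init__(self) -> None:
        if self.layers[0].name != "input":
            raise ValueError("first layer must be 'input'")
        if self.layers[-1].name != "class_output":
            raise ValueError("last layer must be 'class_output'")
        if self.layers[-2].name != "softmax":
            raise ValueError("softmax must precede class_output")
        if self.layers[-1].out_shape != (self.n_classes,):
            raise ValueError("class_output size must equal n_classes")


def default_network_config() -> NetworkConfig:
    """The canonical 18-layer configuration.

    Kernel geometry is chosen to reproduce the declared shapes exactly:
    conv1 11x11 stride 4 pad 5, pools 3x3 (stride 2 pad 1, then stride 1
    pad 1), conv2 3x3 stride 2 pad 1.  Note pool2 is shape-preserving.
    """
    c = 48
    return NetworkConfig(layers=(
        LayerSpec("input", (200, 100, 3)),
        LayerSpec("convolution", (50, 25, c), {"kernel": 11, "stride": 4, "pad": 5}),
        LayerSpec("relu", (50, 25, c)),
        LayerSpec("normalization", (50, 25, c), {"window": 5}),
        LayerSpec("maxpooling", (25, 13, c), {"kernel": 3, "stride": 2, "pad": 1}),
        LayerSpec("convolution", (13, 7, c), {"kernel": 3, "stride": 2, "pad": 1}),
        LayerSpec("relu", (13, 7, c)),
        LayerSpec("normalization", (13, 7, c), {"window": 5}),
        LayerSpec("maxpooling", (13, 7, c), {"kernel": 3, "stride": 1, "pad": 1}),
        LayerSpec("fully_connected", (1, 1, 2184)),
        LayerSpec("relu", (1, 1, 2184)),
        LayerSpec("dropout", (1, 1, 2184), {"rate": 0.5}),
        LayerSpec("fully_connected", (1, 1, 2184)),
        LayerSpec("relu", (1, 1, 2184)),
        LayerSpec("dropout", (1, 1, 2184), {"rate": 0.5}),
        LayerSpec("fully_connected", (1, 1, 2)),
        LayerSpec("softmax", (1, 1, 2)),
        LayerSpec("class_output", (2,)),
    ))


@dataclass(frozen=True)
class TrainingConfig:
    """SGDM hyperparameters (canonical defaults)."""

    momentum: float = 0.9
    initial_learning_rate: float = 6e-5
    l2_regularization: float = 1e-4
    gradient_threshold_method: str = "l2norm"
    gradient_threshold: float = np.inf
    max_epochs: int = 100
    mini_batch_size: int = 128
    seed: int = 0
    validation_patience: int | None = None
    log_every: int = 20  # iterations between log rows


LOG_COLUMNS = ("Epoch", "Iteration", "Time Elapsed", "Mini-Batch Accuracy",
               "Validation Accuracy", "Mini-Batch Loss", "Validation Loss")


@dataclass
class TrainingLog:
    rows: list[tuple] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def add(self, epoch, iteration, elapsed, mb_acc, val_acc, mb_loss, val_loss):
        self.rows.append((epoch, iteration, elapsed, mb_acc, val_acc,
                          mb_loss, val_loss))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=list(LOG_COLUMNS))

    def save(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @property
    def final_validation_accuracy(self) -> float:
        return self.rows[-1][4]


def _hwc_to_chw(shape_hwc: tuple[int, ...]) -> tuple[int, ...]:
    if len(shape_hwc) == 3:
        h, w, c = shape_hwc
        return (c, h, w)
    return shape_hwc


class Network:
    """Feed-forward CNN with explicit forward/backward passes."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        self.layers: list[L.Layer] = []
        self.class_names = LABELS
        self.input_mean: np.ndarray | None = None
        self.initialized = False
        self._build()

    def _build(self) -> None:
        specs = self.config.layers
        shape = _hwc_to_chw(specs[0].out_shape)  # (C, H, W)
        in_hwc = specs[0].out_shape
        if in_hwc != INPUT_SHAPE:
            raise NetworkBuildError(
                f"layer 1 (input): expected shape {INPUT_SHAPE}, got {in_hwc}"
            )
        flattened = False
        for i, spec in enumerate(specs[1:], start=2):
            kind = spec.name
            p = spec.params
            if kind == "convolution":
                layer = L.Conv2D(shape[0], spec.out_shape[2], p["kernel"],
                                 p["stride"], p["pad"],
                                 weight_sd=p.get("weight_sd"),
                                 input_grad=any(isinstance(l, L.Conv2D)
                                                for l in self.layers))
            elif kind == "relu":
                layer = L.ReLU()
            elif kind == "normalization":
                layer = L.CrossChannelLRN(window=p.get("window", 5))
            elif kind == "maxpooling":
                layer = L.MaxPool(p["kernel"], p["stride"], p.get("pad", 0))
            elif kind == "fully_connected":
                if not flattened:
                    self.layers.append(L.Flatten())
                    shape = self.layers[-1].out_shape(shape)
                    flattened = True
                layer = L.Dense(shape[0], spec.out_shape[-1],
                                weight_sd=p.get("weight_sd"))
            elif kind == "dropout":
                layer = L.Dropout(p.get("rate", 0.5))
            elif kind in ("softmax", "class_output"):
                continue  # softmax/argmax are applied in the loss/predict path
            else:
                raise NetworkBuildError(f"layer {i}: unknown kind {kind!r}")
            shape = layer.out_shape(shape)
            declared = spec.out_shape
            realized = (shape[1], shape[2], shape[0]) if len(shape) == 3 else \
                (1, 1, shape[0])
            if tuple(realized) != tuple(declared):
                raise NetworkBuildError(
                    f"layer {i} ({kind}): realized shape {realized} deviates "
                    f"from declared {declared}"
                )
            self.layers.append(layer)

    def initialize(self, seed: int) -> None:
        rng = np.random.default_rng(seed)
        for layer in self.layers:
            layer.initialize(rng)
        for j, layer in enumerate(self.layers):
            if isinstance(layer, L.Dropout):
                layer.reseed(seed + 1000 + j)
        self.initialized = True

    # -- inference ---------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dlogits: np.ndarray) -> None:
        g = dlogits
        for layer in reversed(self.layers):
            g = layer.backward(g)
            if g is None:
                break

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        if not self.initialized:
            raise RuntimeError("network is not trained/initialized")
        return L.softmax(self.forward(self._center(x), train=False))

    def _center(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if self.input_mean is not None:
            x = x - self.input_mean
        return x

    def layer_output_shapes(self) -> list[tuple[str, tuple[int, ...]]]:
        """(kind, HWC shape) per configured layer, as asserted at build."""
        return [(s.name, s.out_shape) for s in self.config.layers]

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        arrays = {}
        for i, layer in enumerate(self.layers):
            for name, value, _ in layer.params():
                arrays[f"layer{i}_{name}"] = value
        if self.input_mean is not None:
            arrays["input_mean"] = self.input_mean
        arrays["initialized"] = np.array(int(self.initialized))
        np.savez(path, **arrays)

    def load_weights(self, path: str | Path) -> None:
        data = np.load(path)
        for i, layer in enumerate(self.layers):
            for name, value, _ in layer.params():
                value[...] = data[f"layer{i}_{name}"]
        if "input_mean" in data:
            self.input_mean = data["input_mean"]
        self.initialized = bool(data["initialized"])


def build_network(config: NetworkConfig | None = None) -> Network:
    """Instantiate the CNN, asserting every declared layer shape."""
    return Network(config or default_network_config())


# ---------------------------------------------------------------------------
# training

def dataset_to_arrays(dataset: LabeledDataset) -> tuple[np.ndarray, np.ndarray]:
    """Stack a dataset into (N, 3, H, W) float32 inputs and int labels.

    Grayscale crops are replicated across the three input channels.
    """
    h, w, _ = INPUT_SHAPE
    xs = np.empty((len(dataset), 3, h, w), dtype=np.float32)
    ys = np.empty(len(dataset), dtype=np.int64)
    for i, s in enumerate(dataset):
        if s.image.shape != (h, w):
            raise ValueError(
                f"sample {i} has shape {s.image.shape}; expected {(h, w)} "
                "(standardize_resolution first)"
            )
        xs[i] = s.image.astype(np.float32)[None, :, :]
        ys[i] = LABELS.index(s.label)
    return xs, ys


def _format_elapsed(seconds: float) -> str:
    seconds = int(seconds)
    return f"{seconds // 3600:02d}:{(seconds % 3600) // 60:02d}:{seconds % 60:02d}"


def _evaluate(network: Network, x: np.ndarray, y: np.ndarray,
              batch: int = 128) -> tuple[float, float]:
    """(accuracy %, mean cross-entropy) without dropout."""
    losses, correct = [], 0
    for i in range(0, len(x), batch):
        logits = network.forward(x[i:i + batch], train=False)
        probs = L.softmax(logits)
        losses.append(L.cross_entropy(probs, y[i:i + batch]) * len(probs))
        correct += int((probs.argmax(axis=1) == y[i:i + batch]).sum())
    return 100.0 * correct / len(x), float(np.sum(losses) / len(x))


def train(
    network: Network,
    train_set: LabeledDataset,
    val_set: LabeledDataset,
    config: TrainingConfig | None = None,
    batch_hook: Callable[[int, np.ndarray], None] | None = None,
) -> tuple[Network, TrainingLog]:
    """Fit the network with mini-batch SGDM; returns it with a training log.

    ``batch_hook(iteration, sample_indices)`` is invoked once per
    mini-batch with the dataset indices it contained (used to audit that
    an epoch touches every sample exactly once).
    """
    config = config or TrainingConfig()
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("train and validation sets must be nonempty")
    log = TrainingLog()
    batch_size = config.mini_batch_size
    if batch_size > len(train_set):
        log.warnings.append(
            f"mini_batch_size {batch_size} exceeds training-set size "
            f"{len(train_set)}; using a single full batch"
        )
        batch_size = len(train_set)

    x_train, y_train = dataset_to_arrays(train_set)
    x_val, y_val = dataset_to_arrays(val_set)

    network.initialize(config.seed)
    network.input_mean = x_train.mean(axis=0, keepdims=True)
    x_train = x_train - network.input_mean
    x_val = x_val - network.input_mean

    params = [t for layer in network.layers for t in layer.params()]
    velocity = [np.zeros_like(v) for _, v, _ in params]
    lam = config.l2_regularization
    lr = config.initial_learning_rate
    shuffle_rng = np.random.default_rng(config.seed + 1)

    t0 = time.monotonic()
    iteration = 0
    best_val_loss = np.inf
    patience_left = config.validation_patience
    stop = False
    n = len(x_train)

    for epoch in range(1, config.max_epochs + 1):
        order = shuffle_rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            iteration += 1
            if batch_hook is not None:
                batch_hook(iteration, idx)
            xb, yb = x_train[idx], y_train[idx]

            logits = network.forward(xb, train=True)
            probs = L.softmax(logits)
            mb_loss = L.cross_entropy(probs, yb)
            mb_acc = 100.0 * float((probs.argmax(axis=1) == yb).mean())
            network.backward(L.softmax_ce_grad(probs, yb))

            grads = []
            for (name, value, grad), vel in zip(params, velocity):
                g = grad
                if lam and name == "w":
                    g = g + lam * value
                grads.append((value, g, vel))
            if np.isfinite(config.gradient_threshold):
                if config.gradient_threshold_method != "l2norm":
                    raise ValueError("only l2norm clipping is supported")
                total = np.sqrt(sum(float((g * g).sum()) for _, g, _ in grads))
                if total > config.gradient_threshold:
                    scale = config.gradient_threshold / total
                    grads = [(v, g * scale, vel) for v, g, vel in grads]
            for value, g, vel in grads:
                vel *= config.momentum
                vel -= lr * g
                value += vel

            last = epoch == config.max_epochs and start + batch_size >= n
            if iteration == 1 or iteration % config.log_every == 0 or last:
                val_acc, val_loss = _evaluate(network, x_val, y_val)
                log.add(epoch, iteration, _format_elapsed(time.monotonic() - t0),
                        round(mb_acc, 2), round(val_acc, 2),
                        round(mb_loss, 4), round(val_loss, 4))
                if patience_left is not None:
                    if val_loss < best_val_loss - 1e-6:
                        best_val_loss = val_loss
                        patience_left = config.validation_patience
                    else:
                        patience_left -= 1
                        if patience_left <= 0:
                            stop = True
            if stop:
                break
        if stop:
            break

    if not log.rows or log.rows[-1][1] != iteration:
        val_acc, val_loss = _evaluate(network, x_val, y_val)
        log.add(epoch, iteration, _format_elapsed(time.monotonic() - t0),
                round(mb_acc, 2), round(val_acc, 2),
                round(mb_loss, 4), round(val_loss, 4))
    return network, log


def predict(network: Network, image: np.ndarray) -> tuple[np.ndarray, str]:
    """Class probabilities and argmax label for one grayscale crop.

    The crop is resized to the network input resolution if needed; ties
    go to the first class.
    """
    h, w, _ = INPUT_SHAPE
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("predict expects a single 2-D grayscale image")
    if img.shape != (h, w):
        from skimage.transform import resize
        img = resize(img.astype(np.float64), (h, w), order=1,
                     preserve_range=True, anti_aliasing=True)
    x = np.repeat(img.astype(np.float32)[None, None, :, :], 3, axis=1)
    probs = network.predict_proba(x)[0]
    return probs, network.class_names[int(np.argmax(probs))]
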
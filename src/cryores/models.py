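"""The three classifier architectures and their training loop.

* ``dnn`` — global 3-class dense network: flatten, two hidden layers of
  1000 and 100 ReLU units, softmax over {high, medium, low}.
* ``cnn3d`` — global 3-class convolutional network: 32 7x7x7 filters
  (ELU), 64 and 128 5x5x5 filters (ELU, ReLU), each followed by 2x max
  pooling with 'same'-padded convolutions, then a 1024-unit tanh dense
  layer with dropout 0.4 and a softmax head.
* ``unet3d`` — voxel-wise 10-class U-Net on 16-cube patches: four
  encoder levels (two 3x3x3 ReLU convs + channel dropout 0.5 + 2x max
  pool) with 64/128/256/512 filters, a 1024-filter root, a mirrored
  decoder (nearest x2 upsample, 2x2x2 conv, skip concatenation with the
  encoder dropout output, two 3x3x3 convs), and a 1x1x1 softmax head.

Hidden sizes and filter counts are arguments, so desk-scale variants
train in minutes on one CPU while the defaults match the full-size
networks.  Training records validation loss/accuracy each epoch, keeps
the weights of the best (lowest validation loss) epoch, and stops early
once the number of epochs without improvement reaches the patience
(minimum one).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .preprocess import BACKGROUND

__all__ = [
    "TrainConfig",
    "TrainingTrace",
    "build_dnn",
    "build_cnn3d",
    "build_unet3d",
    "build_network",
    "train",
    "predict",
    "predict_proba",
    "save_model",
    "load_model",
]


def build_dnn(
    input_edge: int = 64,
    hidden: tuple[int, int] = (1000, 100),
    n_classes: int = 3,
    seed: int = 0,
):
    """Global 3-class dense classifier on a cubic voxel grid."""
    if input_edge < 2:
        raise ValueError("input_edge must be at least 2")
    rng = np.random.default_rng(seed)
    n_in = input_edge**3
    net = nn.Sequential(
        [
            nn.Flatten(),
            nn.Dense(n_in, hidden[0], rng),
            nn.ReLU(),
            nn.Dense(hidden[0], hidden[1], rng),
            nn.ReLU(),
            nn.Dense(hidden[1], n_classes, rng),
        ]
    )
    net.task = "global"
    net.n_classes = n_classes
    net.spec = {
        "architecture": "dnn",
        "input_edge": input_edge,
        "hidden": list(hidden),
        "n_classes": n_classes,
        "seed": seed,
    }
    return net


def build_cnn3d(
    input_edge: int = 64,
    filters: tuple[int, int, int] = (32, 64, 128),
    dense_units: int = 1024,
    n_classes: int = 3,
    dropout: float = 0.4,
    seed: int = 0,
):
    """Global 3-class 3D convolutional classifier.

    Three conv/pool stages halve the spatial edge three times, so the
    input edge must be divisible by 8.
    """
    if input_edge % 8:
        raise ValueError(f"input edge {input_edge} not divisible by 8")
    rng = np.random.default_rng(seed)
    f1, f2, f3 = filters
    pooled = input_edge // 8
    net = nn.Sequential(
        [
            nn.AddChannel(),
            nn.Conv3D(1, f1, 7, rng),
            nn.ELU(),
            nn.MaxPool3D(),
            nn.Conv3D(f1, f2, 5, rng),
            nn.ELU(),
            nn.MaxPool3D(),
            nn.Conv3D(f2, f3, 5, rng),
            nn.ReLU(),
            nn.MaxPool3D(),
            nn.Flatten(),
            nn.Dense(pooled**3 * f3, dense_units, rng),
            nn.Tanh(),
            nn.Dropout(dropout),
            nn.Dense(dense_units, n_classes, rng),
        ]
    )
    net.task = "global"
    net.n_classes = n_classes
    net.spec = {
        "architecture": "cnn3d",
        "input_edge": input_edge,
        "filters": list(filters),
        "dense_units": dense_units,
        "n_classes": n_classes,
        "dropout": dropout,
        "seed": seed,
    }
    return net


class UNet3D:
    """Voxel-wise classifier: encoder/decoder with skip concatenations.

    The skip taken at each encoder level is the channel-dropout output
    (the last layer before pooling); the decoder joins it with the
    2-cube conv applied to the upsampled deeper features.
    """

    task = "voxel"

    def __init__(
        self,
        input_edge: int = 16,
        filters: tuple[int, ...] = (64, 128, 256, 512, 1024),
        n_classes: int = 10,
        dropout: float = 0.5,
        seed: int = 0,
    ):
        levels = len(filters) - 1
        if input_edge % (2**levels):
            raise ValueError(
                f"input edge {input_edge} cannot be pooled {levels} times"
            )
        rng = np.random.default_rng(seed)
        self.input_edge = input_edge
        self.n_classes = n_classes
        self.filters = tuple(filters)
        self.enc_blocks = []
        self.pools = []
        c_in = 1
        for f in filters[:-1]:
            self.enc_blocks.append(
                [
                    nn.Conv3D(c_in, f, 3, rng),
                    nn.ReLU(),
                    nn.Conv3D(f, f, 3, rng),
                    nn.ReLU(),
                    nn.SpatialDropout3D(dropout),
                ]
            )
            self.pools.append(nn.MaxPool3D())
            c_in = f
        froot = filters[-1]
        self.root = [
            nn.Conv3D(c_in, froot, 3, rng),
            nn.ReLU(),
            nn.Conv3D(froot, froot, 3, rng),
            nn.ReLU(),
            nn.SpatialDropout3D(dropout),
        ]
        self.dec_blocks = []
        c_in = froot
        for f in reversed(filters[:-1]):
            self.dec_blocks.append(
                {
                    "up": nn.Upsample3D(),
                    "conv_up": nn.Conv3D(c_in, f, 2, rng),
                    "act_up": nn.ReLU(),
                    "post": [
                        nn.Conv3D(2 * f, f, 3, rng),
                        nn.ReLU(),
                        nn.Conv3D(f, f, 3, rng),
                        nn.ReLU(),
                    ],
                }
            )
            c_in = f
        self.head = nn.Conv3D(c_in, n_classes, 1, rng)
        self.spec = {
            "architecture": "unet3d",
            "input_edge": input_edge,
            "filters": list(filters),
            "n_classes": n_classes,
            "dropout": dropout,
            "seed": seed,
        }

    # -- plumbing -----------------------------------------------------
    def _all_layers(self):
        for block in self.enc_blocks:
            yield from block
        yield from self.pools
        yield from self.root
        for dec in self.dec_blocks:
            yield dec["up"]
            yield dec["conv_up"]
            yield dec["act_up"]
            yield from dec["post"]
        yield self.head

    def params(self):
        return [p for layer in self._all_layers() for p in layer.params]

    def grads(self):
        return [g for layer in self._all_layers() for g in layer.grads]

    def count_params(self) -> int:
        return sum(p.size for p in self.params())

    def get_weights(self):
        return [p.copy() for p in self.params()]

    def set_weights(self, weights):
        for p, w in zip(self.params(), weights, strict=True):
            p[...] = w

    def seed_dropout(self, seed: int) -> None:
        for i, layer in enumerate(self._all_layers()):
            if isinstance(layer, nn.Dropout):
                layer.rng = np.random.default_rng(seed + 1000 * (i + 1))

    # -- computation --------------------------------------------------
    def forward(self, x, training=False):
        if x.ndim == 4:
            x = x[:, None]
        h = x.astype(np.float32, copy=False)
        self._skips = []
        for block, pool in zip(self.enc_blocks, self.pools):
            for layer in block:
                h = layer.forward(h, training=training)
            self._skips.append(h)
            h = pool.forward(h, training=training)
        for layer in self.root:
            h = layer.forward(h, training=training)
        for dec, skip in zip(self.dec_blocks, reversed(self._skips)):
            h = dec["up"].forward(h, training=training)
            h = dec["conv_up"].forward(h, training=training)
            h = dec["act_up"].forward(h, training=training)
            h = np.concatenate([skip, h], axis=1)
            for layer in dec["post"]:
                h = layer.forward(h, training=training)
        return self.head.forward(h, training=training)

    def backward(self, grad_out):
        g = self.head.backward(grad_out)
        skip_grads = [None] * len(self.enc_blocks)
        n_levels = len(self.enc_blocks)
        for j in range(len(self.dec_blocks) - 1, -1, -1):
            dec = self.dec_blocks[j]
            for layer in reversed(dec["post"]):
                g = layer.backward(g)
            f = self._skips[n_levels - 1 - j].shape[1]
            skip_grads[n_levels - 1 - j] = g[:, :f]
            g = dec["act_up"].backward(g[:, f:])
            g = dec["conv_up"].backward(g)
            g = dec["up"].backward(g)
        for layer in reversed(self.root):
            g = layer.backward(g)
        for i in range(n_levels - 1, -1, -1):
            g = self.pools[i].backward(g) + skip_grads[i]
            for layer in reversed(self.enc_blocks[i]):
                g = layer.backward(g)
        return g


def build_unet3d(
    input_edge: int = 16,
    filters: tuple[int, ...] = (64, 128, 256, 512, 1024),
    n_classes: int = 10,
    dropout: float = 0.5,
    seed: int = 0,
) -> UNet3D:
    """Voxel-wise 10-class 3D U-Net (see module docstring)."""
    return UNet3D(input_edge, filters, n_classes, dropout, seed)


_BUILDERS = {"dnn": build_dnn, "cnn3d": build_cnn3d, "unet3d": build_unet3d}


def build_network(architecture: str, **kwargs):
    try:
        builder = _BUILDERS[architecture]
    except KeyError:
        raise ValueError(f"unknown architecture {architecture!r}") from None
    return builder(**kwargs)


@dataclass
class TrainConfig:
    """Optimizer and schedule settings for one training run.

    The defaults favor desk-scale runs (Adam); ``optimizer='sgd'`` with
    ``learning_rate=0.01`` gives plain constant-rate gradient descent.
    """

    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 32
    patience: int = 50
    max_epochs: int = 100
    weight_decay: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch size must be at least 1")
        if self.patience < 0:
            raise ValueError("patience must be non-negative")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class TrainingTrace:
    """Per-epoch validation history; best epoch = argmin validation loss."""

    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    best_epoch: int = 0

    def __len__(self) -> int:
        return len(self.val_loss)


def _check_labels(net, y: np.ndarray, x: np.ndarray) -> None:
    if net.task == "global":
        if y.ndim != 1 or len(y) != len(x):
            raise ValueError(
                "global classifier expects one integer class per map; got "
                f"labels of shape {y.shape} for {len(x)} inputs"
            )
    else:
        if y.shape != x.shape[: y.ndim] and y.shape != x.shape:
            raise ValueError(
                "voxel classifier expects a label cube per input cube; got "
                f"labels {y.shape} for inputs {x.shape}"
            )


def _loss_and_grad(net, logits, y):
    if net.task == "global":
        return nn.sparse_softmax_cross_entropy(logits, y)
    return nn.voxel_softmax_cross_entropy(logits, y, background=BACKGROUND)


def _accuracy(net, logits, y) -> float:
    if net.task == "global":
        return float((logits.argmax(axis=1) == y).mean())
    pred = logits.argmax(axis=1)
    valid = y != BACKGROUND
    return float((pred[valid] == y[valid]).mean())


def evaluate_batched(net, x, y, batch_size: int = 32):
    """Validation loss and accuracy without updating weights."""
    losses, weights, correct, total = [], [], 0, 0
    for i in range(0, len(x), batch_size):
        xb, yb = x[i : i + batch_size], y[i : i + batch_size]
        logits = net.forward(xb, training=False)
        loss, _ = _loss_and_grad(net, logits, yb)
        if net.task == "global":
            n_items = len(yb)
            correct += int((logits.argmax(axis=1) == yb).sum())
        else:
            valid = yb != BACKGROUND
            n_items = int(valid.sum())
            correct += int((logits.argmax(axis=1)[valid] == yb[valid]).sum())
        losses.append(loss * n_items)
        weights.append(n_items)
        total += n_items
    return sum(losses) / total, correct / total


def train(net, train_set, val_set, config: TrainConfig) -> TrainingTrace:
    """Mini-batch training with per-epoch validation and early stopping.

    ``train_set``/``val_set`` are ``(inputs, labels)`` pairs.  Stops at
    ``max_epochs`` or once ``max(patience, 1)`` consecutive epochs pass
    without a new minimum of the validation loss; the best epoch's
    weights are restored before returning.  Fully reproducible given
    ``config.seed`` on a fixed device.
    """
    x_train, y_train = train_set
    x_val, y_val = val_set
    if len(x_train) == 0 or len(x_val) == 0:
        raise ValueError("training and validation sets must be non-empty")
    _check_labels(net, np.asarray(y_train), np.asarray(x_train))
    _check_labels(net, np.asarray(y_val), np.asarray(x_val))

    x_train = np.asarray(x_train, dtype=np.float32)
    x_val = np.asarray(x_val, dtype=np.float32)
    y_train = np.asarray(y_train)
    y_val = np.asarray(y_val)

    optimizer = (
        nn.Adam(config.learning_rate, weight_decay=config.weight_decay)
        if config.optimizer == "adam"
        else nn.SGD(config.learning_rate, weight_decay=config.weight_decay)
    )
    rng = np.random.default_rng(config.seed)
    net.seed_dropout(config.seed)

    trace = TrainingTrace()
    best_loss = np.inf
    best_weights = net.get_weights()
    allowed_wait = max(config.patience, 1)
    params, grads = net.params(), net.grads()

    for epoch in range(config.max_epochs):
        order = rng.permutation(len(x_train))
        for i in range(0, len(order), config.batch_size):
            idx = order[i : i + config.batch_size]
            logits = net.forward(x_train[idx], training=True)
            _, dlogits = _loss_and_grad(net, logits, y_train[idx])
            net.backward(dlogits)
            optimizer.step(params, grads)
        val_loss, val_acc = evaluate_batched(net, x_val, y_val, config.batch_size)
        trace.val_loss.append(val_loss)
        trace.val_acc.append(val_acc)
        if val_loss < best_loss:
            best_loss = val_loss
            trace.best_epoch = epoch
            best_weights = net.get_weights()
        if epoch - trace.best_epoch >= allowed_wait:
            break
    net.set_weights(best_weights)
    return trace


def predict_proba(net, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
    """Softmax probabilities: (N, K) for global nets, (N, K, D, H, W) voxel-wise."""
    x = np.asarray(x, dtype=np.float32)
    out = []
    for i in range(0, len(x), batch_size):
        logits = net.forward(x[i : i + batch_size], training=False)
        axis = 1
        out.append(nn.softmax(logits, axis=axis))
    return np.concatenate(out, axis=0)


def predict(net, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
    """Predicted classes; ties break to the lowest class index (argmax)."""
    x = np.asarray(x, dtype=np.float32)
    out = []
    for i in range(0, len(x), batch_size):
        logits = net.forward(x[i : i + batch_size], training=False)
        out.append(logits.argmax(axis=1))
    return np.concatenate(out, axis=0)


def save_model(net, path: str | Path) -> None:
    """Save architecture JSON + weights (npz) under a common stem."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(net.spec, fh, indent=2)
    np.savez(path.with_suffix(".npz"), *net.get_weights())


def load_model(path: str | Path):
    path = Path(path)
    with open(path.with_suffix(".json")) as fh:
        spec = dict(json.load(fh))
    architecture = spec.pop("architecture")
    for key in ("hidden", "filters"):
        if key in spec:
            spec[key] = tuple(spec[key])
    net = build_network(architecture, **spec)
    with np.load(path.with_suffix(".npz")) as data:
        net.set_weights([data[k] for k in data.files])
    return net
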
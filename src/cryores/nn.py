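"""Minimal NumPy layer stack for the volumetric classifiers.

Implements exactly the pieces the three architectures need — dense and
3D convolutional layers (stride 1, 'same' padding), 2x max pooling,
nearest-neighbor upsampling, element and channel dropout, softmax
cross-entropy losses, and SGD/Adam — with explicit forward/backward
passes on ``float32`` arrays.  Volumes use channels-first layout
``(N, C, D, H, W)``.

Convolutions run as im2col GEMMs on the forward pass (chunked over the
batch to bound the column buffer) and as per-kernel-offset GEMMs on the
backward pass, which avoids materializing the full column matrix twice.
All weight initialization draws from a caller-supplied seeded generator,
so training is bit-reproducible on a fixed device.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Dense",
    "Conv3D",
    "MaxPool3D",
    "Upsample3D",
    "Flatten",
    "AddChannel",
    "ReLU",
    "ELU",
    "Tanh",
    "Dropout",
    "SpatialDropout3D",
    "Sequential",
    "softmax",
    "sparse_softmax_cross_entropy",
    "voxel_softmax_cross_entropy",
    "SGD",
    "Adam",
]


class Layer:
    """Base class: stateless unless it declares ``params``/``grads``."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / n_in)  # He initialization
        self.w = rng.standard_normal((n_in, n_out), dtype=np.float32) * np.float32(scale)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, training=False):
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad_out):
        self.grads[0][...] = self._x.T @ grad_out
        self.grads[1][...] = grad_out.sum(axis=0)
        return grad_out @ self.w.T


def _same_pad(k: int) -> tuple[int, int]:
    total = k - 1
    return total // 2, total - total // 2


class Conv3D(Layer):
    """3D convolution, stride 1, 'same' zero padding, He init."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        fan_in = c_in * kernel**3
        scale = np.sqrt(2.0 / fan_in)
        self.w = rng.standard_normal(
            (c_out, c_in, kernel, kernel, kernel), dtype=np.float32
        ) * np.float32(scale)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.kernel = kernel
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, training=False):
        k = self.kernel
        lo, hi = _same_pad(k)
        xp = np.pad(x, ((0, 0), (0, 0), (lo, hi), (lo, hi), (lo, hi)))
        self._xp = xp
        n, c_in, d, h, w = x.shape
        c_out = self.w.shape[0]
        w_mat = self.w.reshape(c_out, -1).T  # (c_in*k^3, c_out)
        out = np.empty((n, c_out, d, h, w), dtype=self.w.dtype)
        # chunk the batch so the column buffer stays under ~256 MB
        vox = d * h * w
        chunk = max(1, int(6.4e7 // max(1, vox * c_in * k**3)))
        for i in range(0, n, chunk):
            view = np.lib.stride_tricks.sliding_window_view(
                xp[i : i + chunk], (k, k, k), axis=(2, 3, 4)
            )  # (nc, c_in, d, h, w, k, k, k)
            cols = (
                view.transpose(0, 2, 3, 4, 1, 5, 6, 7)
                .reshape(-1, c_in * k**3)
                .astype(self.w.dtype, copy=False)
            )
            res = cols @ w_mat + self.b
            out[i : i + chunk] = res.reshape(-1, d, h, w, c_out).transpose(0, 4, 1, 2, 3)
        return out

    def backward(self, grad_out):
        k = self.kernel
        lo, hi = _same_pad(k)
        xp = self._xp
        n, c_out, d, h, w = grad_out.shape
        c_in = self.w.shape[1]
        go = grad_out.transpose(0, 2, 3, 4, 1).reshape(-1, c_out)  # (n*dhw, c_out)
        dxp = np.zeros_like(xp)
        dw = self.grads[0]
        dw[...] = 0.0
        for di in range(k):
            for dj in range(k):
                for dk in range(k):
                    patch = xp[:, :, di : di + d, dj : dj + h, dk : dk + w]
                    pm = patch.transpose(0, 2, 3, 4, 1).reshape(-1, c_in)
                    dw[:, :, di, dj, dk] += go.T @ pm
                    contrib = go @ self.w[:, :, di, dj, dk]  # (n*dhw, c_in)
                    dxp[:, :, di : di + d, dj : dj + h, dk : dk + w] += (
                        contrib.reshape(n, d, h, w, c_in).transpose(0, 4, 1, 2, 3)
                    )
        self.grads[1][...] = go.sum(axis=0)
        return dxp[
            :, :, lo : xp.shape[2] - hi, lo : xp.shape[3] - hi, lo : xp.shape[4] - hi
        ]


class MaxPool3D(Layer):
    """2x2x2 max pooling with stride 2."""

    def forward(self, x, training=False):
        n, c, d, h, w = x.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError(f"spatial dims {x.shape[2:]} not divisible by 2")
        blocks = x.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
        flat = blocks.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(n, c, d // 2, h // 2, w // 2, 8)
        self._argmax = flat.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(flat, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, grad_out):
        n, c, d2, h2, w2 = grad_out.shape
        flat = np.zeros((n, c, d2, h2, w2, 8), dtype=grad_out.dtype)
        np.put_along_axis(flat, self._argmax[..., None], grad_out[..., None], axis=-1)
        blocks = flat.reshape(n, c, d2, h2, w2, 2, 2, 2).transpose(0, 1, 2, 5, 3, 6, 4, 7)
        return blocks.reshape(self._in_shape)


class Upsample3D(Layer):
    """Nearest-neighbor x2 upsampling."""

    def forward(self, x, training=False):
        return x.repeat(2, axis=2).repeat(2, axis=3).repeat(2, axis=4)

    def backward(self, grad_out):
        n, c, d, h, w = grad_out.shape
        blocks = grad_out.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
        return blocks.sum(axis=(3, 5, 7))


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad_out):
        return grad_out.reshape(self._shape)


class AddChannel(Layer):
    """Insert the singleton channel axis: (N, D, H, W) -> (N, 1, D, H, W)."""

    def forward(self, x, training=False):
        return x[:, None]

    def backward(self, grad_out):
        return grad_out[:, 0]


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad_out):
        return grad_out * self._mask


class ELU(Layer):
    def __init__(self, alpha: float = 1.0):
        super().__init__()
        self.alpha = alpha

    def forward(self, x, training=False):
        self._out = np.where(x > 0, x, self.alpha * np.expm1(x))
        return self._out

    def backward(self, grad_out):
        return grad_out * np.where(self._out > 0, 1.0, self._out + self.alpha)


class Tanh(Layer):
    def forward(self, x, training=False):
        self._out = np.tanh(x)
        return self._out

    def backward(self, grad_out):
        return grad_out * (1.0 - self._out**2)


class Dropout(Layer):
    """Inverted element dropout; identity at inference."""

    def __init__(self, rate: float):
        super().__init__()
        self.rate = rate
        self.rng = np.random.default_rng(0)

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, grad_out):
        if self._mask is None:
            return grad_out
        return grad_out * self._mask


class SpatialDropout3D(Dropout):
    """Drops whole channels (one Bernoulli draw per (sample, channel))."""

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape[:2]) < keep).astype(np.float32) / keep
        self._mask = mask[:, :, None, None, None]
        return x * self._mask


class Sequential:
    """A plain layer chain with aggregated parameters."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, grad_out):
        for layer in reversed(self.layers):
            grad_out = layer.backward(grad_out)
        return grad_out

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def count_params(self) -> int:
        return sum(p.size for p in self.params())

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params(), weights, strict=True):
            p[...] = w

    def seed_dropout(self, seed: int) -> None:
        for i, layer in enumerate(self.layers):
            if isinstance(layer, Dropout):
                layer.rng = np.random.default_rng(seed + 1000 * (i + 1))

    def dropout_layers(self) -> list[Layer]:
        return [l for l in self.layers if isinstance(l, Dropout)]


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def sparse_softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over integer labels; returns (loss, dlogits)."""
    n = len(labels)
    p = softmax(logits, axis=1)
    eps = 1e-12
    loss = -np.log(p[np.arange(n), labels] + eps).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), (dlogits / n).astype(np.float32)


def voxel_softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray, background: int = -1
) -> tuple[float, np.ndarray]:
    """Per-voxel categorical cross-entropy, excluding background voxels.

    ``logits``: (N, K, D, H, W); ``labels``: (N, D, H, W) integers with
    ``background`` marking voxels outside the structure mask.
    """
    valid = labels != background
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("no in-mask voxels to compute loss over")
    p = softmax(logits, axis=1)
    safe = np.where(valid, labels, 0)
    picked = np.take_along_axis(p, safe[:, None], axis=1)[:, 0]
    eps = 1e-12
    loss = -(np.log(picked + eps) * valid).sum() / n_valid
    one_hot = np.zeros_like(p)
    np.put_along_axis(one_hot, safe[:, None], 1.0, axis=1)
    dlogits = (p - one_hot) * valid[:, None] / n_valid
    return float(loss), dlogits.astype(np.float32)


class SGD:
    """Plain gradient descent with a constant learning rate.

    ``weight_decay`` adds an L2 penalty gradient before the update.
    """

    def __init__(self, lr: float, weight_decay: float = 0.0):
        self.lr = lr
        self.weight_decay = weight_decay

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        for p, g in zip(params, grads):
            if self.weight_decay:
                g = g + self.weight_decay * p
            p -= self.lr * g


class Adam:
    def __init__(
        self,
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self._m: list[np.ndarray] | None = None
        self._v: list[np.ndarray] | None = None
        self._t = 0

    def step(self, params, grads):
        if self._m is None:
            self._m = [np.zeros_like(p) for p in params]
            self._v = [np.zeros_like(p) for p in params]
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        correction = np.sqrt(1 - b2**self._t) / (1 - b1**self._t)
        for p, g, m, v in zip(params, grads, self._m, self._v):
            if self.weight_decay:
                g = g + self.weight_decay * p
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            p -= self.lr * correction * m / (np.sqrt(v) + self.eps)
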
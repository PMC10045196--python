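"""Minimal CPU neural-network layers with explicit backpropagation.

Activations use a single-sample layout: ``float32`` arrays of shape
``(channels, height, width)``. Each layer caches what its backward pass
needs when ``train=True``; callers must pair every ``forward`` with at
most one ``backward`` before the next training step. Parameter gradients
accumulate until :meth:`Layer.zero_grad`.

The dense-prediction losses used throughout the package make a batch
dimension unnecessary: every image already contributes tens of
thousands of pixel terms per step.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base class; layers without parameters leave ``params`` empty."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k in self.grads:
            self.grads[k][...] = 0.0


class Conv2d(Layer):
    """Same-padded 2-D convolution (stride 1), He-initialised.

    Computed as a single (out_ch, k*k*in_ch) x (k*k*in_ch, H*W) matrix
    product against a column matrix assembled from the k*k shifted
    views of the padded input (offset-major row order, so the weight
    tensor is transposed to (out, k, k, in) before flattening).
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        fan_in = in_ch * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch, kernel, kernel))
        self.params = {"W": w.astype(np.float32), "b": np.zeros(out_ch, np.float32)}
        self.grads = {"W": np.zeros_like(self.params["W"]), "b": np.zeros_like(self.params["b"])}
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, int, int] | None = None

    def _wmat(self) -> np.ndarray:
        # (out, k, k, in) flattened to match the offset-major column rows
        return np.ascontiguousarray(
            self.params["W"].transpose(0, 2, 3, 1)).reshape(self.out_ch, -1)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        c, h, w = x.shape
        if c != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {c}")
        k = self.kernel
        p = k // 2
        x = x.astype(np.float32, copy=False)
        xp = np.pad(x, ((0, 0), (p, p), (p, p))) if p else x
        cols = np.empty((k * k * c, h * w), np.float32)
        for i, (dy, dx) in enumerate((a, b) for a in range(k) for b in range(k)):
            cols[i * c:(i + 1) * c] = xp[:, dy:dy + h, dx:dx + w].reshape(c, h * w)
        y = self._wmat() @ cols + self.params["b"][:, None]
        if train:
            self._cols, self._shape = cols, (c, h, w)
        return y.reshape(self.out_ch, h, w)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        if self._cols is None or self._shape is None:
            raise RuntimeError("backward called before forward(train=True)")
        c, h, w = self._shape
        k = self.kernel
        p = k // 2
        gy_flat = np.ascontiguousarray(gy.reshape(self.out_ch, h * w), dtype=np.float32)
        gwmat = gy_flat @ self._cols.T  # (out, k*k*in)
        self.grads["W"] += gwmat.reshape(self.out_ch, k, k, c).transpose(0, 3, 1, 2)
        self.grads["b"] += gy_flat.sum(axis=1)
        gcols = self._wmat().T @ gy_flat  # (k*k*in, h*w)
        gxp = np.zeros((c, h + 2 * p, w + 2 * p), np.float32)
        for i, (dy, dx) in enumerate((a, b) for a in range(k) for b in range(k)):
            gxp[:, dy:dy + h, dx:dx + w] += gcols[i * c:(i + 1) * c].reshape(c, h, w)
        self._cols = None
        return gxp[:, p:p + h, p:p + w] if p else gxp


class ReLU(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        mask = x > 0
        if train:
            self._mask = mask
        return np.where(mask, x, 0.0).astype(np.float32, copy=False)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, gy, 0.0).astype(np.float32, copy=False)


class MaxPool2d(Layer):
    """Non-overlapping max pooling; spatial sides must be divisible by k."""

    def __init__(self, k: int) -> None:
        super().__init__()
        self.k = k
        self._idx: np.ndarray | None = None
        self._shape: tuple[int, int, int] | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        c, h, w = x.shape
        k = self.k
        if h % k or w % k:
            raise ValueError(f"pooling a {h}x{w} map by {k} requires divisible sides")
        xr = x.reshape(c, h // k, k, w // k, k).transpose(0, 1, 3, 2, 4).reshape(c, h // k, w // k, k * k)
        idx = xr.argmax(axis=-1)
        y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx, self._shape = idx, (c, h, w)
        return np.ascontiguousarray(y)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        c, h, w = self._shape
        k = self.k
        g = np.zeros((c, h // k, w // k, k * k), np.float32)
        np.put_along_axis(g, self._idx[..., None], gy[..., None].astype(np.float32), axis=-1)
        return g.reshape(c, h // k, w // k, k, k).transpose(0, 1, 3, 2, 4).reshape(c, h, w)


class UpsampleNearest(Layer):
    """Nearest-neighbour upsampling by an integer factor."""

    def __init__(self, k: int) -> None:
        super().__init__()
        self.k = k

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return np.repeat(np.repeat(x, self.k, axis=1), self.k, axis=2)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        c, hk, wk = gy.shape
        k = self.k
        return gy.reshape(c, hk // k, k, wk // k, k).sum(axis=(2, 4)).astype(np.float32)


class ConvBlock(Layer):
    """Two same-padded convolutions, each followed by ReLU."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv2d(in_ch, out_ch, kernel, rng)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(out_ch, out_ch, kernel, rng)
        self.relu2 = ReLU()

    @property
    def sublayers(self) -> list[Layer]:
        return [self.conv1, self.relu1, self.conv2, self.relu2]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.sublayers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, gy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.sublayers):
            gy = layer.backward(gy)
        return gy

    def zero_grad(self) -> None:
        for layer in self.sublayers:
            layer.zero_grad()


def sigmoid(z: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out.astype(np.float32)


def collect_parameter_layers(layers) -> list[Layer]:
    """Flatten a nested iterable of layers into those carrying parameters."""
    flat: list[Layer] = []
    for layer in layers:
        if isinstance(layer, ConvBlock):
            flat.extend(l for l in layer.sublayers if l.params)
        elif isinstance(layer, Layer) and layer.params:
            flat.append(layer)
    return flat
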
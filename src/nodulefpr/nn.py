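"""A compact 3D conv-net engine on numpy with explicit backpropagation.

Implements exactly the layers the false-positive-reduction classifier
needs: same-padded 3×3×3 convolution (im2col + BLAS matmul), leaky ReLU,
2× max pooling with floor division, inverted dropout, global average
pooling, dense layers, and an Adam optimizer with decoupled weight decay.
Gradients are verified against finite differences in the test suite.

Layers cache what their backward pass needs during a training-mode forward;
a backward call must therefore follow its matching forward.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Layer",
    "Conv3d",
    "LeakyReLU",
    "MaxPool3d",
    "Dropout",
    "GlobalAvgPool",
    "Dense",
    "Sequential",
    "Adam",
    "sigmoid",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Layer:
    """Base layer: forward/backward plus parameter bookkeeping."""

    def forward(self, x: np.ndarray, train: bool, rng: Optional[np.random.Generator]) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> List[Dict]:
        """List of {'name', 'value', 'grad', 'decay'} parameter slots."""
        return []

    def zero_grad(self) -> None:
        for p in self.params():
            p["grad"][...] = 0.0


class Conv3d(Layer):
    """3×3×3 convolution, stride 1, zero 'same' padding."""

    KERNEL = 3

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator,
                 leaky_slope: float = 0.01):
        k = self.KERNEL
        fan_in = in_channels * k**3
        # He initialisation adjusted for the leaky slope
        std = np.sqrt(2.0 / (fan_in * (1.0 + leaky_slope**2)))
        self.w = rng.normal(0.0, std, size=(out_channels, in_channels * k**3)).astype(np.float32)
        self.b = np.zeros(out_channels, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self._cols: Optional[np.ndarray] = None
        self._shape: Optional[Tuple[int, ...]] = None

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, c, d, h, w = x.shape
        k = self.KERNEL
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
        # win: (n, c, d, h, w, k, k, k) -> (n*d*h*w, c*k^3)
        cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(n * d * h * w, c * k**3)
        return np.ascontiguousarray(cols, dtype=np.float32)

    def forward(self, x, train, rng):
        n, c, d, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {c}")
        cols = self._im2col(x)
        y = cols @ self.w.T + self.b
        self._cols = cols if train else None
        self._shape = x.shape
        return np.ascontiguousarray(
            y.reshape(n, d, h, w, self.out_channels).transpose(0, 4, 1, 2, 3)
        )

    def backward(self, grad):
        n, co, d, h, w = grad.shape
        g2 = grad.transpose(0, 2, 3, 4, 1).reshape(n * d * h * w, co)
        self.gw += (g2.T @ self._cols).astype(np.float32)
        self.gb += g2.sum(axis=0).astype(np.float32)
        gcols = (g2 @ self.w).reshape(n, d, h, w, self.in_channels, 3, 3, 3)
        gx = np.zeros((n, self.in_channels, d + 2, h + 2, w + 2), dtype=np.float32)
        for dz in range(3):
            for dy in range(3):
                for dx in range(3):
                    gx[:, :, dz:dz + d, dy:dy + h, dx:dx + w] += (
                        gcols[:, :, :, :, :, dz, dy, dx].transpose(0, 4, 1, 2, 3)
                    )
        self._cols = None
        return gx[:, :, 1:-1, 1:-1, 1:-1]

    def params(self):
        return [
            {"name": "w", "value": self.w, "grad": self.gw, "decay": True},
            {"name": "b", "value": self.b, "grad": self.gb, "decay": False},
        ]


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01):
        self.slope = slope
        self._mask = None

    def forward(self, x, train, rng):
        mask = x >= 0
        self._mask = mask
        return np.where(mask, x, self.slope * x).astype(np.float32)

    def backward(self, grad):
        return np.where(self._mask, grad, self.slope * grad).astype(np.float32)


class MaxPool3d(Layer):
    """2× max pooling per axis with floor division (odd trailing voxels are
    dropped, so e.g. a 15-slice extent pools 15 → 7 → 3 → 1)."""

    def __init__(self):
        self._cache = None

    def forward(self, x, train, rng):
        n, c, d, h, w = x.shape
        do, ho, wo = d // 2, h // 2, w // 2
        if min(do, ho, wo) < 1:
            raise ValueError(f"extent {x.shape[2:]} too small to pool")
        xc = x[:, :, : 2 * do, : 2 * ho, : 2 * wo]
        xr = xc.reshape(n, c, do, 2, ho, 2, wo, 2)
        xr = xr.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(n, c, do, ho, wo, 8)
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        self._cache = (x.shape, idx)
        return np.ascontiguousarray(out)

    def backward(self, grad):
        (n, c, d, h, w), idx = self._cache
        do, ho, wo = d // 2, h // 2, w // 2
        g8 = np.zeros((n, c, do, ho, wo, 8), dtype=np.float32)
        np.put_along_axis(g8, idx[..., None], grad[..., None].astype(np.float32), axis=-1)
        g8 = g8.reshape(n, c, do, ho, wo, 2, 2, 2).transpose(0, 1, 2, 5, 3, 6, 4, 7)
        gx = np.zeros((n, c, d, h, w), dtype=np.float32)
        gx[:, :, : 2 * do, : 2 * ho, : 2 * wo] = g8.reshape(n, c, 2 * do, 2 * ho, 2 * wo)
        return gx


class Dropout(Layer):
    """Inverted dropout: active only in training mode."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self._mask = None

    def forward(self, x, train, rng):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        mask = (rng.uniform(size=x.shape) < keep).astype(np.float32) / keep
        self._mask = mask
        return x * mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class GlobalAvgPool(Layer):
    """Mean over the spatial extent: (n, c, d, h, w) → (n, c)."""

    def forward(self, x, train, rng):
        self._shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, grad):
        n, c, d, h, w = self._shape
        return np.broadcast_to(
            grad[:, :, None, None, None] / (d * h * w), self._shape
        ).astype(np.float32)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 leaky_slope: float = 0.01):
        std = np.sqrt(2.0 / (in_features * (1.0 + leaky_slope**2)))
        self.w = rng.normal(0.0, std, size=(out_features, in_features)).astype(np.float32)
        self.b = np.zeros(out_features, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._x = None

    def forward(self, x, train, rng):
        self._x = x if train else None
        return x @ self.w.T + self.b

    def backward(self, grad):
        self.gw += (grad.T @ self._x).astype(np.float32)
        self.gb += grad.sum(axis=0).astype(np.float32)
        self._x = None
        return (grad @ self.w).astype(np.float32)

    def params(self):
        return [
            {"name": "w", "value": self.w, "grad": self.gw, "decay": False},
            {"name": "b", "value": self.b, "grad": self.gb, "decay": False},
        ]


class Sequential:
    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = False,
                rng: Optional[np.random.Generator] = None) -> np.ndarray:
        if train and rng is None:
            raise ValueError("training-mode forward needs an rng for dropout")
        for layer in self.layers:
            x = layer.forward(x, train, rng)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self) -> List[Dict]:
        return [p for layer in self.layers for p in layer.params()]

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    def state_arrays(self) -> Dict[str, np.ndarray]:
        out = {}
        for li, layer in enumerate(self.layers):
            for p in layer.params():
                out[f"layer{li}_{p['name']}"] = p["value"]
        return out

    def load_state_arrays(self, arrays: Dict[str, np.ndarray]) -> None:
        for li, layer in enumerate(self.layers):
            for p in layer.params():
                key = f"layer{li}_{p['name']}"
                src = arrays[key]
                if src.shape != p["value"].shape:
                    raise ValueError(f"shape mismatch for {key}")
                p["value"][...] = src


class Adam:
    """Adam with decoupled weight decay applied to decay-flagged parameters
    (the convolution kernels)."""

    def __init__(self, params: List[Dict], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p["value"]) for p in params]
        self.v = [np.zeros_like(p["value"]) for p in params]

    def step(self) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p["grad"]
            m[...] = self.beta1 * m + (1.0 - self.beta1) * g
            v[...] = self.beta2 * v + (1.0 - self.beta2) * g * g
            update = (m / b1c) / (np.sqrt(v / b2c) + self.eps)
            if p["decay"] and self.weight_decay > 0:
                update = update + self.weight_decay * p["value"]
            p["value"][...] = p["value"] - self.lr * update
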
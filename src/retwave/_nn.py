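"""Minimal NumPy neural-network engine used by the encoder and readouts.

Implements exactly what the pipeline needs: 3x3/1x1 convolutions (im2col),
ReLU, average pooling, linear layers, residual blocks, He fan-in
initialization, reverse-mode gradients, and Adam.  Everything is float32 and
deterministic given the construction RNG.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


class Layer:
    tag: Optional[str] = None  # e.g. "block:block1" or "relu:relu2"

    def params(self) -> List[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError


# ---------------------------------------------------------------------------
# im2col helpers
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    B, C, OH, OW = win.shape[:4]
    cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(B, C * k * k, OH * OW)
    return np.ascontiguousarray(cols), (OH, OW)


def _col2im(cols: np.ndarray, x_shape, k: int, stride: int, pad: int,
            out_hw: Tuple[int, int]) -> np.ndarray:
    B, C, H, W = x_shape
    OH, OW = out_hw
    dx = np.zeros((B, C, H + 2 * pad, W + 2 * pad), dtype=cols.dtype)
    cols = cols.reshape(B, C, k, k, OH, OW)
    for i in range(k):
        for j in range(k):
            dx[:, :, i:i + stride * OH:stride, j:j + stride * OW:stride] += cols[:, :, i, j]
    if pad:
        dx = dx[:, :, pad:-pad, pad:-pad]
    return dx


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class Conv2d(Layer):
    def __init__(self, in_ch: int, out_ch: int, k: int, stride: int, pad: int,
                 rng: np.random.Generator):
        fan_in = in_ch * k * k
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                  size=(out_ch, fan_in)))
        self.b = Param(np.zeros(out_ch))
        self.k, self.stride, self.pad = k, stride, pad
        self.in_ch, self.out_ch = in_ch, out_ch

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=True):
        cols, (OH, OW) = _im2col(x, self.k, self.stride, self.pad)
        if train:
            self._cache = (cols, x.shape, (OH, OW))
        y = np.einsum("of,bfl->bol", self.W.value, cols, optimize=True)
        y += self.b.value[None, :, None]
        return y.reshape(x.shape[0], self.out_ch, OH, OW)

    def backward(self, g):
        cols, x_shape, out_hw = self._cache
        B = g.shape[0]
        gl = g.reshape(B, self.out_ch, -1)
        self.W.grad += np.einsum("bol,bfl->of", gl, cols, optimize=True)
        self.b.grad += gl.sum(axis=(0, 2))
        dcols = np.einsum("of,bol->bfl", self.W.value, gl, optimize=True)
        return _col2im(dcols, x_shape, self.k, self.stride, self.pad, out_hw)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=True):
        if train:
            self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, g):
        self.W.grad += self._x.T @ g
        self.b.grad += g.sum(axis=0)
        return g @ self.W.value.T


class ReLU(Layer):
    def forward(self, x, train=True):
        y = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, g):
        return g * self._mask


class AvgPool2d(Layer):
    """Non-overlapping 2x2 average pooling (even spatial dims assumed)."""

    def forward(self, x, train=True):
        B, C, H, W = x.shape
        if train:
            self._shape = x.shape
        return x.reshape(B, C, H // 2, 2, W // 2, 2).mean(axis=(3, 5))

    def backward(self, g):
        B, C, H, W = self._shape
        return np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) / 4.0


class GlobalAvgPool(Layer):
    def forward(self, x, train=True):
        if train:
            self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, g):
        B, C, H, W = self._shape
        return np.broadcast_to(g[:, :, None, None], self._shape) / (H * W)


class Flatten(Layer):
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class ResidualBlock(Layer):
    """conv3x3 -> ReLU -> conv3x3, added to a (possibly projected) skip path."""

    def __init__(self, in_ch: int, out_ch: int, stride: int,
                 rng: np.random.Generator):
        self.conv1 = Conv2d(in_ch, out_ch, 3, stride, 1, rng)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(out_ch, out_ch, 3, 1, 1, rng)
        self.proj = (Conv2d(in_ch, out_ch, 1, stride, 0, rng)
                     if (stride != 1 or in_ch != out_ch) else None)
        self.relu_out = ReLU()

    def params(self):
        ps = self.conv1.params() + self.conv2.params()
        if self.proj is not None:
            ps += self.proj.params()
        return ps

    def forward(self, x, train=True):
        h = self.relu1.forward(self.conv1.forward(x, train), train)
        h = self.conv2.forward(h, train)
        skip = x if self.proj is None else self.proj.forward(x, train)
        return self.relu_out.forward(h + skip, train)

    def backward(self, g):
        g = self.relu_out.backward(g)
        g_skip = g if self.proj is None else self.proj.backward(g)
        g_main = self.conv2.backward(g)
        g_main = self.conv1.backward(self.relu1.backward(g_main))
        return g_main + g_skip


class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def forward_collect(self, x, want_tags: Iterable[str]) -> Dict[str, np.ndarray]:
        """Inference pass returning outputs of layers whose tag is wanted."""
        want = set(want_tags)
        out: Dict[str, np.ndarray] = {}
        for layer in self.layers:
            x = layer.forward(x, train=False)
            if layer.tag is not None and layer.tag in want:
                out[layer.tag] = x
        out["__final__"] = x
        return out


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params: Sequence[Param], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * np.square(p.grad)
            p.value -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


# ---------------------------------------------------------------------------
# Loss helpers
# ---------------------------------------------------------------------------

def softmax_xent(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy and gradient w.r.t. logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = -np.log(probs[np.arange(n), labels] + 1e-12).mean()
    grad = probs
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n
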
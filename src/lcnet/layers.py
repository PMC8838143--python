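"""Minimal CNN layer library on numpy with explicit backpropagation.

All layers operate on (B, C, H, W) float batches and implement
``forward(x, training)`` plus ``backward(grad_out) -> grad_in``,
caching whatever the backward pass needs.  Convolution is evaluated as
an im2col patch-matrix product so the heavy lifting is a single BLAS
matmul per layer; its input gradient is reconstructed with k*k strided
slice-adds (col2im).

Gradients of every layer are validated against central finite
differences in the test suite; that check, not an autodiff framework,
is the correctness authority here.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Module",
    "Conv2d",
    "BatchNorm2d",
    "LeakyReLU",
    "MaxPool2",
    "AvgPool2",
    "GlobalAvgPool",
    "Linear",
    "Sequential",
    "ConcatUnit",
    "softmax",
    "softmax_cross_entropy",
]


class Param:
    """A learnable array with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Module:
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[tuple[str, Param]]:
        return []

    def __call__(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.forward(x, training)


def _same_padding(size: int, k: int, stride: int) -> tuple[int, int, int]:
    """(out_size, pad_begin, pad_end) for 'same' semantics: out = ceil(in/stride)."""
    out = -(-size // stride)
    total = max((out - 1) * stride + k - size, 0)
    return out, total // 2, total - total // 2


class Conv2d(Module):
    """2-D convolution (cross-correlation) with bias.

    Weight layout (out_ch, in_ch, k, k); He fan-in initialization with
    the LeakyReLU gain, drawn from the generator passed in so a seed
    fixes every weight in the network.
    """

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel_size: int,
        stride: int = 1,
        padding: str = "same",
        rng: np.random.Generator | None = None,
        dtype=np.float32,
        init_slope: float = 0.3,
    ):
        if padding not in ("same", "valid"):
            raise ValueError(f"padding must be 'same' or 'valid', got {padding!r}")
        self.in_ch, self.out_ch = in_ch, out_ch
        self.k, self.stride, self.padding = kernel_size, stride, padding
        rng = rng or np.random.default_rng()
        fan_in = in_ch * kernel_size * kernel_size
        gain = np.sqrt(2.0 / (1.0 + init_slope**2))
        w = rng.normal(0.0, gain / np.sqrt(fan_in), size=(out_ch, in_ch, kernel_size, kernel_size))
        self.weight = Param(w.astype(dtype))
        self.bias = Param(np.zeros(out_ch, dtype=dtype))
        self._cache = None

    def params(self):
        return [("weight", self.weight), ("bias", self.bias)]

    def _geometry(self, h: int, w: int):
        if self.padding == "same":
            ho, pt, pb = _same_padding(h, self.k, self.stride)
            wo, pl, pr = _same_padding(w, self.k, self.stride)
        else:
            ho = (h - self.k) // self.stride + 1
            wo = (w - self.k) // self.stride + 1
            pt = pb = pl = pr = 0
        return ho, wo, (pt, pb), (pl, pr)

    def forward(self, x, training=False):
        b, c, h, w = x.shape
        if c != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {c}")
        ho, wo, (pt, pb), (pl, pr) = self._geometry(h, w)
        if pt or pb or pl or pr:
            xp = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
        else:
            xp = x
        win = np.lib.stride_tricks.sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        win = win[:, :, :: self.stride, :: self.stride]  # (B, C, Ho, Wo, k, k)
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            b * ho * wo, c * self.k * self.k
        )
        wmat = self.weight.value.reshape(self.out_ch, -1)
        out = cols @ wmat.T + self.bias.value
        out = out.reshape(b, ho, wo, self.out_ch).transpose(0, 3, 1, 2)
        if training:
            self._cache = (cols, (b, c, h, w), (ho, wo), (pt, pb, pl, pr))
        return np.ascontiguousarray(out)

    def backward(self, grad):
        cols, (b, c, h, w), (ho, wo), (pt, pb, pl, pr) = self._cache
        self._cache = None
        gmat = np.ascontiguousarray(grad.transpose(0, 2, 3, 1)).reshape(b * ho * wo, self.out_ch)
        self.weight.grad += (gmat.T @ cols).reshape(self.weight.value.shape)
        self.bias.grad += gmat.sum(axis=0)
        dcols = (gmat @ self.weight.value.reshape(self.out_ch, -1)).reshape(
            b, ho, wo, c, self.k, self.k
        )
        dxp = np.zeros((b, c, h + pt + pb, w + pl + pr), dtype=grad.dtype)
        s = self.stride
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += dcols[
                    :, :, :, :, i, j
                ].transpose(0, 3, 1, 2)
        return dxp[:, :, pt : pt + h, pl : pl + w]


class BatchNorm2d(Module):
    """Per-channel batch normalization with learned scale and offset."""

    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5, dtype=np.float32):
        self.ch, self.momentum, self.eps = ch, momentum, eps
        self.gamma = Param(np.ones(ch, dtype=dtype))
        self.beta = Param(np.zeros(ch, dtype=dtype))
        self.running_mean = np.zeros(ch, dtype=dtype)
        self.running_var = np.ones(ch, dtype=dtype)
        self._cache = None

    def params(self):
        return [("gamma", self.gamma), ("beta", self.beta)]

    def forward(self, x, training=False):
        g = self.gamma.value[None, :, None, None]
        b = self.beta.value[None, :, None, None]
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(
                self.running_mean.dtype
            )
            self.running_var = ((1 - m) * self.running_var + m * var).astype(
                self.running_var.dtype
            )
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        if training:
            self._cache = (xhat, inv_std)
        return (g * xhat + b).astype(x.dtype)

    def backward(self, grad):
        xhat, inv_std = self._cache
        self._cache = None
        n = grad.shape[0] * grad.shape[2] * grad.shape[3]
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None]
        dxhat = grad * g
        sum_d = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        sum_dx = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (inv_std[None, :, None, None] / n) * (n * dxhat - sum_d - xhat * sum_dx)


class LeakyReLU(Module):
    """x for x >= 0, slope * x for x < 0 (slope 0.3 throughout the network)."""

    def __init__(self, slope: float = 0.3):
        self.slope = slope
        self._mask = None

    def forward(self, x, training=False):
        mask = x < 0
        if training:
            self._mask = mask
        return np.where(mask, self.slope * x, x)

    def backward(self, grad):
        mask, self._mask = self._mask, None
        return np.where(mask, self.slope * grad, grad)


def _pool_windows(x):
    b, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"2x2 pooling needs even spatial size, got {h}x{w}")
    return x.reshape(b, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
        b, c, h // 2, w // 2, 4
    )


class MaxPool2(Module):
    """2x2 max pooling, stride 2; ties resolve to the first window element."""

    def __init__(self):
        self._cache = None

    def forward(self, x, training=False):
        win = _pool_windows(x)
        idx = win.argmax(axis=-1)
        out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
        if training:
            self._cache = (idx, x.shape)
        return out

    def backward(self, grad):
        (idx, shape), self._cache = self._cache, None
        b, c, h, w = shape
        dwin = np.zeros((b, c, h // 2, w // 2, 4), dtype=grad.dtype)
        np.put_along_axis(dwin, idx[..., None], grad[..., None], axis=-1)
        return dwin.reshape(b, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(shape)


class AvgPool2(Module):
    """2x2 average pooling, stride 2."""

    def __init__(self):
        self._shape = None

    def forward(self, x, training=False):
        if training:
            self._shape = x.shape
        return _pool_windows(x).mean(axis=-1)

    def backward(self, grad):
        shape, self._shape = self._shape, None
        b, c, h, w = shape
        dwin = np.broadcast_to((grad / 4.0)[..., None], (b, c, h // 2, w // 2, 4))
        return dwin.reshape(b, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(shape)


class GlobalAvgPool(Module):
    """Collapse each feature map to its spatial mean: (B,C,H,W) -> (B,C)."""

    def __init__(self):
        self._shape = None

    def forward(self, x, training=False):
        if training:
            self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        shape, self._shape = self._shape, None
        b, c, h, w = shape
        return np.broadcast_to(grad[:, :, None, None], shape) / (h * w)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng()
        w = rng.normal(0.0, 1.0 / np.sqrt(in_features), size=(out_features, in_features))
        self.weight = Param(w.astype(dtype))
        self.bias = Param(np.zeros(out_features, dtype=dtype))
        self._x = None

    def params(self):
        return [("weight", self.weight), ("bias", self.bias)]

    def forward(self, x, training=False):
        if training:
            self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, grad):
        x, self._x = self._x, None
        self.weight.grad += grad.T @ x
        self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.value


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.modules = list(modules)

    def forward(self, x, training=False):
        for m in self.modules:
            x = m.forward(x, training)
        return x

    def backward(self, grad):
        for m in reversed(self.modules):
            grad = m.backward(grad)
        return grad

    def params(self):
        out = []
        for i, m in enumerate(self.modules):
            out.extend((f"{i}.{n}", p) for n, p in m.params())
        return out


class ConcatUnit(Module):
    """Parallel branches on one input, concatenated along channels.

    With ``include_input`` the (un-transformed) input is appended as a
    final passthrough slice — the stem junction of the network, where
    the pooled stem features join the first two blocks' outputs.
    Concatenation requires identical spatial sizes across branches;
    a mismatch raises immediately.
    """

    def __init__(self, branches: list[Module], include_input: bool = False):
        self.branches = branches
        self.include_input = include_input
        self._splits = None

    def forward(self, x, training=False):
        outs = [br.forward(x, training) for br in self.branches]
        if self.include_input:
            outs.append(x)
        spatial = {o.shape[2:] for o in outs}
        if len(spatial) != 1:
            raise ValueError(f"concat branches disagree on spatial size: {sorted(spatial)}")
        if training:
            self._splits = [o.shape[1] for o in outs]
        return np.concatenate(outs, axis=1)

    def backward(self, grad):
        splits, self._splits = self._splits, None
        edges = np.cumsum(splits)[:-1]
        parts = np.split(grad, edges, axis=1)
        dx = parts[-1].copy() if self.include_input else 0.0
        n_br = len(self.branches)
        for br, g in zip(self.branches, parts[:n_br]):
            dx = dx + br.backward(np.ascontiguousarray(g))
        return dx

    def params(self):
        out = []
        for i, br in enumerate(self.branches):
            out.extend((f"b{i}.{n}", p) for n, p in br.params())
        return out


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax, numerically stabilized."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray,
    targets_onehot: np.ndarray,
    class_weights: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Weighted cross-entropy fused with softmax.

    Returns (mean loss, gradient w.r.t. logits).  For one-hot targets
    the logit gradient is w_c * (p - t) / N per sample of class c.
    """
    p = softmax(logits)
    n = logits.shape[0]
    w_per_sample = targets_onehot @ class_weights  # weight of each sample's true class
    logp = np.log(np.clip(p, 1e-12, 1.0))
    loss = float(-(w_per_sample * (targets_onehot * logp).sum(axis=1)).sum() / n)
    grad = (w_per_sample[:, None] * (p - targets_onehot) / n).astype(logits.dtype)
    return loss, grad
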
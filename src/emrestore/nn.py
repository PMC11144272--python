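"""Minimal numpy neural-network core: reverse-mode tape, layers, Adam.

The restoration models in this package are small conditional U-Nets run at
patch scale on a CPU, so the network stack is written directly on numpy: a
tape-based autodiff ``Tensor`` supporting exactly the ops the U-Net needs
(same-padded 3x3/1x1 convolution, 2x average pool, 2x nearest upsample,
SiLU, exp/log/clip, concat, matmul), plus an Adam optimizer with named
parameter groups so fine-tuning can freeze the encoder.

Everything is deterministic given the seeds handed in; convolution gradients
are computed as convolutions with the spatially flipped kernel (exact for
stride 1, same padding), avoiding any scatter-add.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "Parameter", "no_grad", "Adam", "Conv2d", "Linear"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling tape construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        data = np.asarray(data)
        if not np.issubdtype(data.dtype, np.floating):
            data = data.astype(np.float64)
        self.data = data
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev = ()

    # -- graph bookkeeping -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(
            p.requires_grad or p._prev for p in parents
        ):
            out._prev = tuple(parents)
            out._backward = backward
            out.requires_grad = True
        return out

    def _accum(self, g):
        g = _unbroadcast(np.asarray(g, dtype=self.data.dtype),
                         self.data.shape)
        self.grad = g if self.grad is None else self.grad + g

    def backward(self):
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # -- elementwise -------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return Tensor._make(
            self.data + other.data, (self, other),
            lambda g: (self._accum(g), other._accum(g)),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: self._accum(-g))

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return Tensor._make(
            self.data * other.data, (self, other),
            lambda g: (self._accum(g * other.data),
                       other._accum(g * self.data)),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self * other ** -1.0

    def __pow__(self, p: float):
        return Tensor._make(
            self.data ** p, (self,),
            lambda g: self._accum(g * p * self.data ** (p - 1)),
        )

    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._make(out_data, (self,),
                            lambda g: self._accum(g * out_data))

    def log(self):
        return Tensor._make(np.log(self.data), (self,),
                            lambda g: self._accum(g / self.data))

    def clip(self, lo: float, hi: float):
        inside = (self.data >= lo) & (self.data <= hi)
        return Tensor._make(np.clip(self.data, lo, hi), (self,),
                            lambda g: self._accum(g * inside))

    def silu(self):
        d = self.data
        s = np.where(d >= 0, 1.0 / (1.0 + np.exp(-np.abs(d))),
                     np.exp(-np.abs(d)) / (1.0 + np.exp(-np.abs(d))))
        return Tensor._make(
            self.data * s, (self,),
            lambda g: self._accum(g * s * (1.0 + self.data * (1.0 - s))),
        )

    # -- reductions / reshaping -------------------------------------------
    def mean(self):
        n = self.data.size
        return Tensor._make(
            np.array(self.data.mean()), (self,),
            lambda g: self._accum(np.broadcast_to(g / n, self.data.shape)),
        )

    def sum(self):
        return Tensor._make(
            np.array(self.data.sum()), (self,),
            lambda g: self._accum(np.broadcast_to(g, self.data.shape)),
        )

    def reshape(self, *shape):
        orig = self.data.shape
        return Tensor._make(self.data.reshape(*shape), (self,),
                            lambda g: self._accum(g.reshape(orig)))

    def mean_axes(self, axes: tuple, keepdims: bool = True):
        n = int(np.prod([self.data.shape[a] for a in axes]))
        out = self.data.mean(axis=axes, keepdims=keepdims)

        def backward(g):
            if not keepdims:
                g = np.expand_dims(g, axes)
            self._accum(np.broadcast_to(g / n, self.data.shape))

        return Tensor._make(out, (self,), backward)

    def __matmul__(self, other):
        return Tensor._make(
            self.data @ other.data, (self, other),
            lambda g: (self._accum(g @ other.data.T),
                       other._accum(self.data.T @ g)),
        )


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


# ---------------------------------------------------------------------------
# spatial ops (NCHW, stride 1, same padding)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N,C,H,W) -> (N*H*W, C*k*k) patch matrix, same padding, stride 1."""
    p = k // 2
    if p:
        x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    n, c = x.shape[:2]
    win = sliding_window_view(x, (k, k), axis=(2, 3))  # N,C,H,W,k,k
    h, wd = win.shape[2], win.shape[3]
    return (np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5))
            .reshape(n * h * wd, c * k * k))


def _conv_raw(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Cross-correlate x (N,C,H,W) with w (O,C,k,k), same padding, stride 1."""
    n, _, h, wd = x.shape
    cols = _im2col(x, w.shape[-1])
    out = cols @ w.reshape(w.shape[0], -1).T
    return out.reshape(n, h, wd, w.shape[0]).transpose(0, 3, 1, 2)


def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-padded stride-1 convolution with per-channel bias."""
    k = w.data.shape[-1]
    n, _, h, wd = x.data.shape
    cols = _im2col(x.data, k)
    out = cols @ w.data.reshape(w.data.shape[0], -1).T
    out = (out.reshape(n, h, wd, -1).transpose(0, 3, 1, 2)
           + b.data.reshape(1, -1, 1, 1))

    def backward(g):
        # dx: correlate g with the flipped, channel-transposed kernel
        w_flip = np.ascontiguousarray(
            w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
        x._accum(_conv_raw(g, w_flip))
        g_rs = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(
            n * h * wd, -1)
        w._accum((g_rs.T @ cols).reshape(w.data.shape))
        b._accum(g.sum(axis=(0, 2, 3)))

    return Tensor._make(out, (x, w, b), backward)


def avg_pool2(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    out = x.data.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(g):
        x._accum(np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) / 4.0)

    return Tensor._make(out, (x,), backward)


def upsample2(x: Tensor) -> Tensor:
    out = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)

    def backward(g):
        n, c, h, w = out.shape
        x._accum(g.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5)))

    return Tensor._make(out, (x,), backward)


def concat_channels(parts: list[Tensor]) -> Tensor:
    sizes = [p.data.shape[1] for p in parts]
    out = np.concatenate([p.data for p in parts], axis=1)

    def backward(g):
        start = 0
        for p, s in zip(parts, sizes):
            p._accum(g[:, start:start + s])
            start += s

    return Tensor._make(out, tuple(parts), backward)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Module:
    """Base class tracking named parameters of nested layers."""

    def parameters(self) -> dict[str, Parameter]:
        out = {}
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                out[name] = val
            elif isinstance(val, Module):
                for k, v in val.parameters().items():
                    out[f"{name}.{k}"] = v
        return out


def spatial_rms_norm(x: Tensor, gain: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-channel RMS normalization over the spatial axes with a learned
    per-channel gain; keeps activations well-scaled at any depth."""
    msq = (x * x).mean_axes((2, 3), keepdims=True)
    return x * (msq + eps) ** -0.5 * gain


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, rng,
                 dtype=np.float32):
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.w = Parameter((rng.standard_normal((c_out, c_in, k, k))
                            * scale).astype(dtype))
        self.b = Parameter(np.zeros(c_out, dtype=dtype))

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng, dtype=np.float32):
        scale = np.sqrt(2.0 / d_in)
        self.w = Parameter((rng.standard_normal((d_in, d_out))
                            * scale).astype(dtype))
        self.b = Parameter(np.zeros(d_out, dtype=dtype))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Adam:
    """Adam over a dict of named parameters; supports group selection."""

    def __init__(self, params: dict[str, Parameter], lr: float,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
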
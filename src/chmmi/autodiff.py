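"""A minimal reverse-mode autodiff tape over numpy arrays.

Implements exactly the operations the detector needs — 2-D convolution via
im2col, batch normalization, SiLU/ReLU/sigmoid, elementwise add/multiply
with broadcasting, channel concatenation, stride-1 max pooling, nearest
2x upsampling, spatial mean, dense maps and a shared-kernel 1-D channel
convolution — each with an analytic backward pass.  Gradients flow through
a topologically sorted tape started by ``Tensor.backward``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Tensor:
    """A numpy array on the autodiff tape."""

    __slots__ = ("data", "grad", "parents", "_backward", "requires_grad")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.parents = tuple(parents)
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients into every tensor on the tape below self."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float32)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, parents=(a, b))

    def bwd(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.shape))

    out._backward = bwd
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data * b.data, parents=(a, b))

    def bwd(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.data, b.shape))

    out._backward = bwd
    return out


def _stable_sigmoid(x: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-x))


def sigmoid(x: Tensor) -> Tensor:
    s = _stable_sigmoid(x.data)
    out = Tensor(s, parents=(x,))

    def bwd(g):
        x._accum(g * s * (1.0 - s))

    out._backward = bwd
    return out


def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0.0), parents=(x,))

    def bwd(g):
        x._accum(g * (x.data > 0))

    out._backward = bwd
    return out


def silu(x: Tensor) -> Tensor:
    s = _stable_sigmoid(x.data)
    out = Tensor(x.data * s, parents=(x,))

    def bwd(g):
        x._accum(g * (s * (1.0 + x.data * (1.0 - s))))

    out._backward = bwd
    return out


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]

    def bwd(g):
        offset = 0
        for t, s in zip(tensors, sizes):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(offset, offset + s)
            if t.requires_grad:
                t._accum(g[tuple(sl)])
            offset += s

    out._backward = bwd
    return out


def _im2col(xp: np.ndarray, k: int, stride: int):
    # xp: padded input (N, C, Hp, Wp) -> columns (N, Ho*Wo, C*k*k)
    win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    N, C, Ho, Wo = win.shape[:4]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(N, Ho * Wo, C * k * k)
    return np.ascontiguousarray(cols), Ho, Wo


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, pad: int = 0) -> Tensor:
    """2-D convolution (cross-correlation); w has shape (Cout, Cin, k, k)."""
    N, C, H, W = x.shape
    Cout, Cin, k, _ = w.shape
    if Cin != C:
        raise ValueError(f"conv2d channel mismatch: input {C}, weight {Cin}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x.data
    cols, Ho, Wo = _im2col(xp, k, stride)
    wmat = w.data.reshape(Cout, -1)
    y = cols @ wmat.T  # (N, Ho*Wo, Cout)
    if b is not None:
        y = y + b.data
    out_data = y.transpose(0, 2, 1).reshape(N, Cout, Ho, Wo)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, parents=parents)

    def bwd(g):
        gmat = g.reshape(N, Cout, Ho * Wo).transpose(0, 2, 1)  # (N, L, Cout)
        if b is not None and b.requires_grad:
            b._accum(gmat.sum(axis=(0, 1)))
        if w.requires_grad:
            dw = np.einsum("nlo,nlk->ok", gmat, cols)
            w._accum(dw.reshape(w.shape))
        if x.requires_grad:
            dcols = gmat @ wmat  # (N, L, C*k*k)
            dcols = dcols.reshape(N, Ho, Wo, C, k, k).transpose(0, 3, 1, 2, 4, 5)
            dxp = np.zeros_like(xp)
            for ki in range(k):
                for kj in range(k):
                    dxp[:, :, ki:ki + stride * Ho:stride,
                        kj:kj + stride * Wo:stride] += dcols[:, :, :, :, ki, kj]
            if pad:
                dxp = dxp[:, :, pad:-pad, pad:-pad]
            x._accum(dxp)

    out._backward = bwd
    return out


def maxpool2d(x: Tensor, k: int) -> Tensor:
    """Stride-1, same-size max pooling (odd k), -inf padded."""
    pad = (k - 1) // 2
    N, C, H, W = x.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)),
                constant_values=-np.inf)
    win = sliding_window_view(xp, (k, k), axis=(2, 3))
    flat = win.reshape(N, C, H, W, k * k)
    idx = flat.argmax(axis=-1)
    out = Tensor(np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0],
                 parents=(x,))

    def bwd(g):
        dxp = np.zeros_like(xp)
        ki, kj = np.divmod(idx, k)
        n_i, c_i, h_i, w_i = np.indices((N, C, H, W), sparse=False)
        np.add.at(dxp, (n_i, c_i, h_i + ki, w_i + kj), g)
        x._accum(dxp[:, :, pad:pad + H, pad:pad + W] if pad else dxp)

    out._backward = bwd
    return out


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling."""
    out = Tensor(x.data.repeat(2, axis=2).repeat(2, axis=3), parents=(x,))
    N, C, H, W = x.shape

    def bwd(g):
        x._accum(g.reshape(N, C, H, 2, W, 2).sum(axis=(3, 5)))

    out._backward = bwd
    return out


def spatial_mean(x: Tensor) -> Tensor:
    """Global average pool: (N, C, H, W) -> (N, C)."""
    N, C, H, W = x.shape
    out = Tensor(x.data.mean(axis=(2, 3)), parents=(x,))

    def bwd(g):
        x._accum(np.broadcast_to(g[:, :, None, None] / (H * W), x.shape))

    out._backward = bwd
    return out


def channel_scale(x: Tensor, w: Tensor) -> Tensor:
    """Multiply each channel of x (N,C,H,W) by the per-sample weight w (N,C)."""
    out = Tensor(x.data * w.data[:, :, None, None], parents=(x, w))

    def bwd(g):
        if x.requires_grad:
            x._accum(g * w.data[:, :, None, None])
        if w.requires_grad:
            w._accum((g * x.data).sum(axis=(2, 3)))

    out._backward = bwd
    return out


def linear(x: Tensor, w: Tensor) -> Tensor:
    """Bias-free dense map: x (N, Cin) @ w.T with w (Cout, Cin)."""
    out = Tensor(x.data @ w.data.T, parents=(x, w))

    def bwd(g):
        if w.requires_grad:
            w._accum(g.T @ x.data)
        if x.requires_grad:
            x._accum(g @ w.data)

    out._backward = bwd
    return out


def conv1d_channels(z: Tensor, kernel: Tensor) -> Tensor:
    """Shared-kernel 1-D convolution across channels: z (N, C), kernel (k,),
    zero-padded so the output keeps length C."""
    k = kernel.shape[0]
    pad = (k - 1) // 2
    N, C = z.shape
    zp = np.pad(z.data, ((0, 0), (pad, pad)))
    win = sliding_window_view(zp, k, axis=1)  # (N, C, k)
    out = Tensor(win @ kernel.data, parents=(z, kernel))

    def bwd(g):
        if kernel.requires_grad:
            kernel._accum(np.einsum("nc,nck->k", g, win))
        if z.requires_grad:
            dzp = np.zeros_like(zp)
            for j in range(k):
                dzp[:, j:j + C] += g * kernel.data[j]
            z._accum(dzp[:, pad:pad + C] if pad else dzp)

    out._backward = bwd
    return out


def batchnorm2d(x: Tensor, gamma: Tensor, beta: Tensor,
                running_mean: np.ndarray, running_var: np.ndarray,
                training: bool, momentum: float = 0.1,
                eps: float = 1e-5) -> Tensor:
    """Batch normalization over (N, H, W) per channel.

    In training mode batch statistics are used and the running buffers are
    updated in place; in eval mode the running buffers are used.
    """
    N, C, H, W = x.shape
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) * inv_std[None, :, None, None]
    out = Tensor(gamma.data[None, :, None, None] * xhat
                 + beta.data[None, :, None, None],
                 parents=(x, gamma, beta))
    m = N * H * W

    def bwd(g):
        if beta.requires_grad:
            beta._accum(g.sum(axis=(0, 2, 3)))
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gs = gamma.data[None, :, None, None] * inv_std[None, :, None, None]
            if training:
                gmean = g.mean(axis=(0, 2, 3))[None, :, None, None]
                gxhat = (g * xhat).mean(axis=(0, 2, 3))[None, :, None, None]
                x._accum(gs * (g - gmean - xhat * gxhat))
            else:
                x._accum(gs * g)

    out._backward = bwd
    return out


class Adam:
    """Adam over a flat list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * g * g
            p.data -= self.lr * (self.m[i] / bc1) / (np.sqrt(self.v[i] / bc2) + self.eps)
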
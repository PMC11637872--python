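"""Network building blocks on top of the autodiff tape.

The vocabulary follows the YOLOv5 family that the detector extends:

* ``CBS`` — Conv + BatchNorm + SiLU, the basic unit.
* ``C3`` — a CSP bottleneck stage: two 1x1 branches, one of which runs a
  residual 3x3 bottleneck, concatenated and fused by a 1x1 conv.
* ``SPPF`` — spatial pyramid pooling (fast): three chained stride-1 5x5 max
  pools concatenated with the input.
* ``SEGate`` — squeeze-excitation channel attention (the shallow gate).
* ``ECAGate`` — efficient channel attention via adaptive-kernel 1-D
  convolution (the deep gate).

All parameter initialization is drawn from a caller-provided numpy
Generator so two builds from the same seed are bit-identical.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .attention import eca_kernel_size
from .autodiff import Tensor


class Module:
    """Base class: recursive parameter collection and named state."""

    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def state_arrays(self) -> list[np.ndarray]:
        """Parameters plus non-trained buffers (BN running stats), in order."""
        out: list[np.ndarray] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v.data)
            elif isinstance(v, Module):
                out.extend(v.state_arrays())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.state_arrays())
            elif isinstance(v, np.ndarray):
                out.append(v)
        return out


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = float(np.sqrt(1.0 / max(1, fan_in)))
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, stride: int, rng,
                 bias: bool = False):
        self.k, self.stride, self.pad = k, stride, (k - 1) // 2
        self.weight = Tensor(_kaiming(rng, (cout, cin, k, k), cin * k * k),
                             requires_grad=True)
        self.bias = (Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True)
                     if bias else None)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.weight, self.bias, self.stride, self.pad)


class BatchNorm2d(Module):
    def __init__(self, c: int):
        self.gamma = Tensor(np.ones(c, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(c, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        return ad.batchnorm2d(x, self.gamma, self.beta,
                              self.running_mean, self.running_var, training)


class CBS(Module):
    """Conv + BatchNorm + SiLU."""

    def __init__(self, cin: int, cout: int, k: int, stride: int, rng):
        self.conv = Conv2d(cin, cout, k, stride, rng)
        self.bn = BatchNorm2d(cout)

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        return ad.silu(self.bn(self.conv(x), training))


class Bottleneck(Module):
    def __init__(self, c: int, rng):
        self.cv1 = CBS(c, c, 1, 1, rng)
        self.cv2 = CBS(c, c, 3, 1, rng)

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        return ad.add(x, self.cv2(self.cv1(x, training), training))


class C3(Module):
    """CSP stage with a single residual bottleneck."""

    def __init__(self, cin: int, cout: int, rng):
        h = max(2, cout // 2)
        self.cv1 = CBS(cin, h, 1, 1, rng)
        self.cv2 = CBS(cin, h, 1, 1, rng)
        self.m = Bottleneck(h, rng)
        self.cv3 = CBS(2 * h, cout, 1, 1, rng)

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        a = self.m(self.cv1(x, training), training)
        b = self.cv2(x, training)
        return self.cv3(ad.concat([a, b], axis=1), training)


class SPPF(Module):
    """Chained 5x5 stride-1 max pools, concatenated and fused."""

    def __init__(self, cin: int, cout: int, rng):
        h = max(2, cin // 2)
        self.cv1 = CBS(cin, h, 1, 1, rng)
        self.cv2 = CBS(4 * h, cout, 1, 1, rng)

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        y = self.cv1(x, training)
        p1 = ad.maxpool2d(y, 5)
        p2 = ad.maxpool2d(p1, 5)
        p3 = ad.maxpool2d(p2, 5)
        return self.cv2(ad.concat([y, p1, p2, p3], axis=1), training)


class SEGate(Module):
    """Squeeze-excitation channel gate: GAP -> W1/ReLU -> W2/sigmoid -> scale.

    Bias-free bottleneck with reduction rate r (hidden width floors to 1).
    """

    def __init__(self, c: int, rng, r: int = 16):
        h = max(1, c // r)
        self.w1 = Tensor(_kaiming(rng, (h, c), c), requires_grad=True)
        self.w2 = Tensor(_kaiming(rng, (c, h), h), requires_grad=True)

    def __call__(self, x: Tensor, training: bool, bypass: bool = False) -> Tensor:
        if bypass:
            return x
        z = ad.spatial_mean(x)
        omega = ad.sigmoid(ad.linear(ad.relu(ad.linear(z, self.w1)), self.w2))
        return ad.channel_scale(x, omega)


class ECAGate(Module):
    """Efficient channel attention: GAP -> shared 1-D conv (adaptive k) ->
    sigmoid -> scale.  No dimensionality reduction."""

    def __init__(self, c: int, rng, gamma: int = 2, b: int = 1):
        k = eca_kernel_size(c, gamma, b)
        self.kernel = Tensor(_kaiming(rng, (k,), k), requires_grad=True)

    def __call__(self, x: Tensor, training: bool, bypass: bool = False) -> Tensor:
        if bypass:
            return x
        z = ad.spatial_mean(x)
        omega = ad.sigmoid(ad.conv1d_channels(z, self.kernel))
        return ad.channel_scale(x, omega)
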
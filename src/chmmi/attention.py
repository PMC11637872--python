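"""Channel-attention operators: squeeze-excitation (SCAM) and efficient
channel attention (DCAM).

Both are pure, shape-preserving transforms on a feature map ``U`` of shape
(C, H, W):

* SCAM (squeeze-excitation): global average pooling per channel gives the
  channel statistic ``z``; a bottleneck gating network
  ``omega = sigmoid(W2 @ relu(W1 @ z))`` (reduction rate r, default 16)
  yields per-channel weights in (0, 1); the output rescales each channel by
  its weight.
* DCAM (efficient channel attention): the bottleneck is replaced by a
  single bias-free 1-D convolution across the channel statistic, with kernel
  size chosen adaptively from the channel count, so no dimensionality
  reduction occurs.

These operators consume the already-convolved feature map; the surrounding
network block owns whatever convolution produced it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _check_map(U: np.ndarray) -> np.ndarray:
    U = np.asarray(U, dtype=float)
    if U.ndim != 3:
        raise ValueError(f"feature map must be (C, H, W), got shape {U.shape}")
    if not np.all(np.isfinite(U)):
        raise ValueError("feature map contains non-finite values")
    return U


def global_average_pool(U: np.ndarray) -> np.ndarray:
    """Channel statistic z: the spatial mean of each channel."""
    U = _check_map(U)
    return U.mean(axis=(1, 2))


@dataclass(frozen=True)
class ScamParams:
    """Bottleneck weights of the squeeze-excitation gate (bias-free).

    W1 maps C -> max(1, C // r), W2 maps back to C; activations are fixed
    (ReLU inside, sigmoid outside).
    """

    W1: np.ndarray
    W2: np.ndarray
    r: int = 16

    @staticmethod
    def init(C: int, r: int = 16, seed: int = 0) -> "ScamParams":
        hidden = max(1, C // r)
        rng = np.random.default_rng(seed)
        scale1 = 1.0 / math.sqrt(C)
        scale2 = 1.0 / math.sqrt(hidden)
        return ScamParams(
            W1=rng.uniform(-scale1, scale1, size=(hidden, C)),
            W2=rng.uniform(-scale2, scale2, size=(C, hidden)),
            r=r,
        )


def scam_excite(z: np.ndarray, params: ScamParams) -> np.ndarray:
    """Gating: omega = sigmoid(W2 @ relu(W1 @ z)); entries lie in (0, 1)."""
    z = np.asarray(z, dtype=float)
    if params.W1.shape[1] != z.shape[0] or params.W2.shape[1] != params.W1.shape[0]:
        raise ValueError(
            f"shape mismatch: z {z.shape}, W1 {params.W1.shape}, W2 {params.W2.shape}"
        )
    hidden = np.maximum(params.W1 @ z, 0.0)
    return _sigmoid(params.W2 @ hidden)


def scam(U: np.ndarray, params: ScamParams) -> np.ndarray:
    """Squeeze-excitation: rescale each channel of U by its learned weight."""
    U = _check_map(U)
    omega = scam_excite(global_average_pool(U), params)
    if omega.shape[0] != U.shape[0]:
        raise ValueError("weight length does not match channel count")
    return omega[:, None, None] * U


def eca_kernel_size(C: int, gamma: int = 2, b: int = 1) -> int:
    """Adaptive 1-D kernel size: the odd integer nearest log2(C)/gamma + b/gamma.

    Ties and even results resolve upward, so wider channel counts always get
    an equal or longer interaction range.  C in {2, 16, 256} gives k in
    {1, 3, 5}.
    """
    if C < 1:
        raise ValueError(f"channel count must be >= 1, got {C}")
    psi = math.log2(C) / gamma + b / gamma
    lower = math.floor(psi)
    lower = lower if lower % 2 == 1 else lower - 1  # largest odd <= psi
    upper = lower + 2
    k = lower if psi - lower < upper - psi else upper  # ties go upward
    return max(1, k)


def conv1d_channels(z: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Bias-free 1-D convolution of the channel statistic, zero-padded to
    keep length C.  A single shared kernel slides across channels."""
    k = kernel.shape[0]
    if k % 2 == 0:
        raise ValueError(f"kernel length must be odd, got {k}")
    pad = (k - 1) // 2
    zp = np.pad(np.asarray(z, dtype=float), pad)
    return np.array([zp[i:i + k] @ kernel for i in range(z.shape[0])])


def dcam(U: np.ndarray, kernel: np.ndarray | None = None,
         gamma: int = 2, b: int = 1, seed: int = 0) -> np.ndarray:
    """Efficient channel attention: omega = sigmoid(conv1d_k(z)), output
    = omega * U channel-wise.  Kernel size k = eca_kernel_size(C); a kernel
    may be supplied (length k) or is initialized from ``seed``."""
    U = _check_map(U)
    C = U.shape[0]
    k = eca_kernel_size(C, gamma, b)
    if kernel is None:
        rng = np.random.default_rng(seed)
        kernel = rng.uniform(-1.0 / math.sqrt(k), 1.0 / math.sqrt(k), size=k)
    kernel = np.asarray(kernel, dtype=float)
    if kernel.shape != (k,):
        raise ValueError(f"kernel must have shape ({k},), got {kernel.shape}")
    z = global_average_pool(U)
    omega = _sigmoid(conv1d_channels(z, kernel))
    return omega[:, None, None] * U
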
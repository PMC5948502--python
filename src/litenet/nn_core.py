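"""From-scratch differentiable 1-D layer kernels.

Every operation here is written directly against numpy arrays, with an
analytic backward pass; the test suite checks each gradient against central
finite differences and each forward pass against a naive loop reference.

Conventions
-----------
* Feature maps are arrays of shape ``(batch, channels, length)``.
* Layer convolutions are **cross-correlations** with "same" zero padding
  (pad ``ceil((k-1)/2)`` left, ``floor((k-1)/2)`` right) and an optional
  stride; with stride ``s`` the output length is ``ceil(L / s)``.  This is
  the length-preserving form that the architecture's channel/length
  bookkeeping relies on.
* :func:`conv1d_full` is the separate, kernel-reversing *full* convolution
  ``y[n] = Σ_k x[k] h[n-k]`` of signal-processing textbooks, kept as its own
  primitive: a length-``m`` input and length-``k`` kernel give a length
  ``m+k-1`` output.
* Dense layers operate on ``(batch, features)``.
* Dropout uses inverted scaling at train time and is the identity at eval.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "conv1d_full",
    "conv_forward", "conv_backward",
    "depthwise_forward", "depthwise_backward",
    "maxpool_forward", "maxpool_backward",
    "leaky_relu", "leaky_relu_backward",
    "dropout_forward", "dropout_backward",
    "dense_forward", "dense_backward",
    "softmax", "cross_entropy",
    "standard_conv_macs", "separable_conv_macs",
]


# ---------------------------------------------------------------------------
# Full (flip-and-slide) convolution

def conv1d_full(x: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Full 1-D convolution with kernel reversal.

    ``y[n] = Σ_j x[j] · h[n-j]`` for ``n = 0 … m+k-2``; e.g. a length-3 input
    against a length-3 kernel yields a length-5 output.
    """
    x = np.asarray(x, dtype=np.float64)
    h = np.asarray(h, dtype=np.float64)
    if x.ndim != 1 or h.ndim != 1 or x.size == 0 or h.size == 0:
        raise ValueError("conv1d_full requires non-empty 1-D input and kernel")
    m, k = x.size, h.size
    y = np.zeros(m + k - 1)
    for j in range(k):  # shift-and-add; equivalent to the double sum
        y[j : j + m] += h[j] * x
    return y


# ---------------------------------------------------------------------------
# "Same"-padded strided cross-correlation (standard / squeeze / pointwise)

def _same_pad(x: np.ndarray, k: int) -> tuple[np.ndarray, int]:
    # even kernels pad the extra zero on the left: k=2 on [1,2,3] gives [1,3,5]
    pad_l = k // 2
    pad_r = (k - 1) // 2
    return np.pad(x, ((0, 0), (0, 0), (pad_l, pad_r))), pad_l


def conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray, stride: int = 1) -> np.ndarray:
    """Multi-channel cross-correlation.

    ``x``: (B, C_in, L); ``W``: (k, C_in, C_out); ``b``: (C_out,).
    Output: (B, C_out, ceil(L / stride)).
    """
    k, c_in, c_out = W.shape
    if x.shape[1] != c_in:
        raise ValueError(f"input has {x.shape[1]} channels, weights expect {c_in}")
    xp, _ = _same_pad(x, k)
    win = sliding_window_view(xp, k, axis=2)  # (B, C_in, L, k)
    win = win[:, :, ::stride, :]
    return np.einsum("bclk,kco->bol", win, W, optimize=True) + b[None, :, None]


def conv_backward(
    x: np.ndarray, W: np.ndarray, stride: int, gy: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of :func:`conv_forward` w.r.t. input, weights and bias."""
    k, c_in, c_out = W.shape
    B, _, L = x.shape
    xp, pad_l = _same_pad(x, k)
    gy_full = np.zeros((B, c_out, L))
    gy_full[:, :, ::stride] = gy
    win_full = sliding_window_view(xp, k, axis=2)  # (B, C_in, L, k)
    gW = np.einsum("bclk,bol->kco", win_full, gy_full, optimize=True)
    gb = gy.sum(axis=(0, 2))
    gxp = np.zeros_like(xp)
    for j in range(k):
        gxp[:, :, j : j + L] += np.einsum("bol,co->bcl", gy_full, W[j], optimize=True)
    return gxp[:, :, pad_l : pad_l + L], gW, gb


# ---------------------------------------------------------------------------
# Depthwise convolution (channel multiplier 1: one kernel per channel)

def depthwise_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray, stride: int = 1) -> np.ndarray:
    """Per-channel cross-correlation; channel j of the output depends only on
    channel j of the input.  ``W``: (k, C); ``b``: (C,)."""
    k, c = W.shape
    if x.shape[1] != c:
        raise ValueError(f"input has {x.shape[1]} channels, depthwise weights expect {c}")
    xp, _ = _same_pad(x, k)
    win = sliding_window_view(xp, k, axis=2)[:, :, ::stride, :]
    return np.einsum("bclk,kc->bcl", win, W, optimize=True) + b[None, :, None]


def depthwise_backward(
    x: np.ndarray, W: np.ndarray, stride: int, gy: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    k, c = W.shape
    B, _, L = x.shape
    xp, pad_l = _same_pad(x, k)
    gy_full = np.zeros((B, c, L))
    gy_full[:, :, ::stride] = gy
    win_full = sliding_window_view(xp, k, axis=2)
    gW = np.einsum("bclk,bcl->kc", win_full, gy_full, optimize=True)
    gb = gy.sum(axis=(0, 2))
    gxp = np.zeros_like(xp)
    for j in range(k):
        gxp[:, :, j : j + L] += gy_full * W[j][None, :, None]
    return gxp[:, :, pad_l : pad_l + L], gW, gb


# ---------------------------------------------------------------------------
# Max pooling (non-overlapping windows; trailing remainder dropped)

def maxpool_forward(x: np.ndarray, k: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Non-overlapping max pooling with window = stride = ``k``.

    Returns ``(y, argmax)``; output length is ``floor(L / k)``.
    """
    B, C, L = x.shape
    if L < k:
        raise ValueError(f"cannot pool length {L} with window {k}")
    L_out = L // k
    xr = x[:, :, : L_out * k].reshape(B, C, L_out, k)
    idx = xr.argmax(axis=3)
    y = np.take_along_axis(xr, idx[..., None], axis=3)[..., 0]
    return y, idx


def maxpool_backward(x_shape: tuple, k: int, idx: np.ndarray, gy: np.ndarray) -> np.ndarray:
    B, C, L = x_shape
    L_out = L // k
    gxr = np.zeros((B, C, L_out, k))
    np.put_along_axis(gxr, idx[..., None], gy[..., None], axis=3)
    gx = np.zeros((B, C, L))
    gx[:, :, : L_out * k] = gxr.reshape(B, C, L_out * k)
    return gx


# ---------------------------------------------------------------------------
# Activations, dropout, dense

def leaky_relu(x: np.ndarray, alpha: float = 0.01) -> np.ndarray:
    """``x`` if ``x >= 0`` else ``alpha * x``, elementwise."""
    return np.where(x >= 0, x, alpha * x)


def leaky_relu_backward(x: np.ndarray, alpha: float, gy: np.ndarray) -> np.ndarray:
    return gy * np.where(x >= 0, 1.0, alpha)


def dropout_forward(
    x: np.ndarray, rate: float, rng: np.random.Generator | None, train: bool
) -> tuple[np.ndarray, np.ndarray | None]:
    """Inverted dropout: at train time keep units with prob ``1-rate`` and
    scale by ``1/(1-rate)``; identity at eval time or at rate 0."""
    if not (0.0 <= rate < 1.0):
        raise ValueError("dropout rate must lie in [0, 1)")
    if not train or rate == 0.0:
        return x, None
    if rng is None:
        raise ValueError("training-mode dropout needs an RNG")
    mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * mask, mask


def dropout_backward(mask: np.ndarray | None, gy: np.ndarray) -> np.ndarray:
    return gy if mask is None else gy * mask


def dense_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Affine map on flattened features: ``x @ W + b``; ``W``: (F, U)."""
    return x @ W + b


def dense_backward(
    x: np.ndarray, W: np.ndarray, gy: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    return gy @ W.T, x.T @ gy, gy.sum(axis=0)


# ---------------------------------------------------------------------------
# Softmax classifier head and cross-entropy loss

def softmax(z: np.ndarray) -> np.ndarray:
    """Row-wise softmax with max-subtraction for overflow safety.

    Shift-invariant: ``softmax(z + c) == softmax(z)``; rows sum to 1 and the
    argmax of the probabilities equals the argmax of the logits.
    """
    z = np.asarray(z, dtype=np.float64)
    squeeze = z.ndim == 1
    z2 = np.atleast_2d(z)
    e = np.exp(z2 - z2.max(axis=1, keepdims=True))
    p = e / e.sum(axis=1, keepdims=True)
    return p[0] if squeeze else p


def cross_entropy(p: np.ndarray, q: np.ndarray, eps: float = 1e-12) -> float:
    """Cross-entropy ``H(p, q) = -Σ p log q`` (natural log), mean over rows.

    ``p`` is the expected distribution (rows must sum to 1 within 1e-6), ``q``
    the predicted one; predictions are clipped at ``eps`` before the log.
    """
    p = np.atleast_2d(np.asarray(p, dtype=np.float64))
    q = np.atleast_2d(np.asarray(q, dtype=np.float64))
    if p.shape != q.shape:
        raise ValueError("p and q must have the same shape")
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("expected distribution rows must sum to 1")
    return float(-(p * np.log(np.clip(q, eps, None))).sum(axis=1).mean())


# ---------------------------------------------------------------------------
# Multiply-accumulate accounting (per output position)

def standard_conv_macs(k: int, c_in: int, c_out: int) -> int:
    """MACs per output time index of a standard convolution."""
    return k * c_in * c_out


def separable_conv_macs(k: int, c_in: int, c_out: int) -> int:
    """MACs per output time index of a depthwise+pointwise factorization."""
    return k * c_in + c_in * c_out
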
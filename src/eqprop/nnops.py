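"""Low-level array primitives: 2-D convolution and max pooling with their adjoints.

Everything here is pure NumPy.  Convolutions are stride-1 cross-correlations
(the deep-learning convention); pooling is non-overlapping max pooling whose
argmax index maps are returned explicitly so that the inverse pooling
(scatter) and the pooled gather can reuse them.  The adjoint operators are
what the dynamics, the vector-field estimators and the backprop-through-time
oracle are built from.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "conv2d",
    "conv2d_input_grad",
    "conv2d_weight_grad",
    "maxpool",
    "unpool",
    "pool_gather",
    "hard_sigmoid",
    "hard_sigmoid_interior",
    "softmax",
]


def _windows(x: np.ndarray, k: int, padding: int) -> np.ndarray:
    """Sliding k x k windows of a padded (B, C, H, W) array -> (B, C, Ho, Wo, k, k)."""
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    return sliding_window_view(x, (k, k), axis=(2, 3))


def conv2d(x: np.ndarray, w: np.ndarray, padding: int = 0) -> np.ndarray:
    """Stride-1 cross-correlation.

    Parameters
    ----------
    x : (B, Cin, H, W)
    w : (Cout, Cin, k, k)

    Returns
    -------
    (B, Cout, H + 2*padding - k + 1, W + 2*padding - k + 1)
    """
    win = _windows(x, w.shape[-1], padding)
    return np.einsum("bchwij,ocij->bohw", win, w, optimize=True)


def conv2d_input_grad(g: np.ndarray, w: np.ndarray, padding: int = 0) -> np.ndarray:
    """Adjoint of ``conv2d`` w.r.t. its input (a.k.a. transpose convolution).

    ``g`` has the shape of the conv output; the result has the shape of the
    conv input.  Identical to convolving ``g`` with the flipped kernel, which
    realizes the ``w-tilde`` (flipped-kernel) operator of the dynamics.
    """
    k = w.shape[-1]
    wf = w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (Cin, Cout, k, k)
    return conv2d(g, wf, padding=k - 1 - padding)


def conv2d_weight_grad(x: np.ndarray, g: np.ndarray, kernel: int, padding: int = 0) -> np.ndarray:
    """Adjoint of ``conv2d`` w.r.t. the kernel.

    ``x`` is the conv input (B, Cin, H, W), ``g`` the upstream array with the
    conv-output shape (B, Cout, Ho, Wo).  Returns (Cout, Cin, kernel, kernel).
    """
    win = _windows(x, kernel, padding)
    return np.einsum("bohw,bchwij->ocij", g, win, optimize=True)


def maxpool(x: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Non-overlapping max pooling (stride == window).

    Returns ``(pooled, idx)`` where ``idx`` holds, per pooling window, the
    flat argmax position in [0, window**2).  Spatial dims must divide evenly.
    """
    b, c, h, w = x.shape
    if h % window or w % window:
        raise ValueError(f"spatial dims ({h},{w}) not divisible by pool window {window}")
    ho, wo = h // window, w // window
    xr = (
        x.reshape(b, c, ho, window, wo, window)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(b, c, ho, wo, window * window)
    )
    idx = xr.argmax(axis=-1)
    pooled = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return pooled, idx


def unpool(v: np.ndarray, idx: np.ndarray, window: int) -> np.ndarray:
    """Scatter pooled values back to the recorded argmax positions (P^-1).

    Zero everywhere except at the argmax of each window, so
    ``maxpool(unpool(v, idx), window)`` recovers ``v`` when v >= 0 wherever
    scattered (always true for states in [0, 1]).
    """
    b, c, ho, wo = v.shape
    out = np.zeros((b, c, ho, wo, window * window), dtype=v.dtype)
    np.put_along_axis(out, idx[..., None], v[..., None], axis=-1)
    return (
        out.reshape(b, c, ho, wo, window, window)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(b, c, ho * window, wo * window)
    )


def pool_gather(x: np.ndarray, idx: np.ndarray, window: int) -> np.ndarray:
    """Gather entries of a full-resolution array at the recorded argmax positions.

    This is the adjoint of ``unpool`` and routes top-down adjoints through the
    shared pooling index maps.
    """
    b, c, h, w = x.shape
    ho, wo = h // window, w // window
    xr = (
        x.reshape(b, c, ho, window, wo, window)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(b, c, ho, wo, window * window)
    )
    return np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]


def hard_sigmoid(x: np.ndarray) -> np.ndarray:
    """sigma(x) = min(1, max(0, x)) — the bounded activation of the dynamics."""
    return np.clip(x, 0.0, 1.0)


def hard_sigmoid_interior(x: np.ndarray) -> np.ndarray:
    """Subgradient mask of the hard sigmoid: 1 on the open interval (0, 1), else 0."""
    return ((x > 0.0) & (x < 1.0)).astype(x.dtype)


def softmax(z: np.ndarray) -> np.ndarray:
    """Row-wise softmax of (B, C) logits, shift-invariant for stability."""
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)
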
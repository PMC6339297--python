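"""Reference implementations of the layer operations used by segmentation networks.

These are the pure numerical primitives — multichannel valid convolution,
ReLU, local response normalization, max pooling, and atrous (dilated)
convolution together with its receptive-field arithmetic.  They exist as
exactly-specified, oracle-testable functions; there is no training, no
weights, no autodiff.

Conventions: a multichannel image is an (M, H, W) array (channels first); a
kernel is an (M, K, K) array.  Convolution here means cross-correlation over
the valid region only (no padding):

    Y[i, j] = sum_m sum_k sum_l W[m, k, l] * X[m, i + k, j + l]

with output shape (H - K + 1, W - K + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import ShapeError

__all__ = [
    "LRNParams",
    "conv2d",
    "relu",
    "local_response_norm",
    "max_pool",
    "atrous_conv2d",
    "zero_inserted_kernel",
    "effective_field_of_view",
    "kernel_parameter_count",
]


@dataclass(frozen=True)
class LRNParams:
    """Local response normalization parameters.

    ``a`` (scaling) and ``b`` (exponent) default to 1e-4 and 0.75; ``size``
    is the full cross-channel window I, so channel i is normalized by
    channels i - I/2 ... i + I/2 (clipped at the channel boundaries).
    """

    a: float = 1e-4
    b: float = 0.75
    size: int = 0

    def __post_init__(self) -> None:
        if self.a < 0:
            raise ValueError("scaling parameter a must be >= 0")
        if self.b <= 0:
            raise ValueError("exponent parameter b must be > 0")
        if self.size < 0 or self.size % 2:
            raise ValueError("channel window size must be even and >= 0")


def _as_3d(x: np.ndarray, what: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ShapeError(f"{what} must be (M, H, W) or (H, W); got shape {arr.shape}")
    return arr


def conv2d(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Valid multichannel cross-correlation of (M, H, W) input with (M, K, K) kernel."""
    x = _as_3d(x, "input")
    w = _as_3d(w, "kernel")
    if x.shape[0] != w.shape[0]:
        raise ShapeError(f"channel mismatch: input has {x.shape[0]}, kernel has {w.shape[0]}")
    if x.shape[1] < w.shape[1] or x.shape[2] < w.shape[2]:
        raise ShapeError(f"input {x.shape[1:]} smaller than kernel {w.shape[1:]}")
    # correlate sums over the channel axis when both arrays span it fully
    out = signal.correlate(x, w, mode="valid", method="direct")
    return out[0]


def relu(x: np.ndarray) -> np.ndarray:
    """Elementwise max(0, x)."""
    return np.maximum(np.asarray(x, dtype=float), 0.0)


def local_response_norm(x: np.ndarray, params: LRNParams = LRNParams()) -> np.ndarray:
    """Cross-channel LRN: each value of channel i divided by (1 + a * sum X_j^2)^b.

    The sum runs over channels i - I/2 ... i + I/2 at the same spatial
    position, clipped at the channel boundaries.
    """
    x = _as_3d(x, "input")
    m = x.shape[0]
    half = params.size // 2
    sq = x * x
    out = np.empty_like(x)
    for i in range(m):
        lo, hi = max(0, i - half), min(m, i + half + 1)
        denom = (1.0 + params.a * sq[lo:hi].sum(axis=0)) ** params.b
        out[i] = x[i] / denom
    return out


def max_pool(x: np.ndarray, window: int, stride: int) -> np.ndarray:
    """Max over window x window sub-regions tiled with the given stride.

    Partial windows at the bottom/right edges are included, so the output
    has ceil(H / stride) x ceil(W / stride) values when window >= stride.
    """
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 2:
        raise ShapeError(f"max_pool expects a 2D raster, got shape {arr.shape}")
    if window < 1 or stride < 1:
        raise ValueError("window and stride must be >= 1")
    h, w = arr.shape
    if window > h or window > w:
        raise ShapeError(f"pool window {window} exceeds raster shape {arr.shape}")
    ys = range(0, h, stride)
    xs = range(0, w, stride)
    out = np.empty((len(ys), len(xs)))
    for oi, y0 in enumerate(ys):
        for oj, x0 in enumerate(xs):
            out[oi, oj] = arr[y0:y0 + window, x0:x0 + window].max()
    return out


def atrous_conv2d(x: np.ndarray, w: np.ndarray, rate: int) -> np.ndarray:
    """Atrous (dilated) cross-correlation: kernel taps sampled at spacing ``rate``.

    Rate 1 reproduces :func:`conv2d` exactly.  The taps are accumulated
    directly at their dilated offsets, which keeps this implementation
    independent of the zero-inserted-kernel construction it is equivalent to.
    """
    x = _as_3d(x, "input")
    w = _as_3d(w, "kernel")
    if rate < 1:
        raise ValueError("atrous rate must be >= 1")
    if x.shape[0] != w.shape[0]:
        raise ShapeError(f"channel mismatch: input has {x.shape[0]}, kernel has {w.shape[0]}")
    m, kh, kw = w.shape
    span_h = effective_field_of_view(kh, rate)
    span_w = effective_field_of_view(kw, rate)
    oh = x.shape[1] - span_h + 1
    ow = x.shape[2] - span_w + 1
    if oh < 1 or ow < 1:
        raise ShapeError(
            f"dilated footprint ({span_h}, {span_w}) exceeds input {x.shape[1:]}"
        )
    out = np.zeros((oh, ow))
    for k in range(kh):
        for l in range(kw):
            tap = x[:, k * rate:k * rate + oh, l * rate:l * rate + ow]
            out += np.einsum("m,mij->ij", w[:, k, l], tap)
    return out


def zero_inserted_kernel(w: np.ndarray, rate: int) -> np.ndarray:
    """Expand an (M, K, K) kernel to its zero-inserted equivalent of side K + (K-1)(rate-1)."""
    w = _as_3d(w, "kernel")
    m, kh, kw = w.shape
    big = np.zeros((m, effective_field_of_view(kh, rate), effective_field_of_view(kw, rate)))
    big[:, ::rate, ::rate] = w
    return big


def effective_field_of_view(kernel_side: int, rate: int) -> int:
    """Side length of the receptive field of a dilated kernel: K + (K-1)(rate-1)."""
    if kernel_side < 1 or rate < 1:
        raise ValueError("kernel side and rate must be >= 1")
    return kernel_side + (kernel_side - 1) * (rate - 1)


def kernel_parameter_count(kernel_side: int) -> int:
    """Free parameters of a K x K (single-channel) kernel: K^2, independent of the atrous rate."""
    if kernel_side < 1:
        raise ValueError("kernel side must be >= 1")
    return kernel_side * kernel_side
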
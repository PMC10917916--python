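"""Low-level array ops shared by the layer implementations.

All activations use NHWC layout (batch, height, width, channels) in float32.
"same" padding follows the ceil-mode convention: the output spatial size of a
stride-``s`` op is ``ceil(H / s)`` and the input is zero-padded as evenly as
possible (extra pixel on the bottom/right when the total padding is odd).
"""

from __future__ import annotations

import numpy as np


def same_pad_amount(size: int, k: int, stride: int) -> tuple[int, int]:
    """Return (before, after) zero padding for ceil-mode 'same' output."""
    out = -(-size // stride)
    total = max((out - 1) * stride + k - size, 0)
    before = total // 2
    return before, total - before


def pad_same(x: np.ndarray, k: int, stride: int, fill: float = 0.0) -> np.ndarray:
    ph = same_pad_amount(x.shape[1], k, stride)
    pw = same_pad_amount(x.shape[2], k, stride)
    if ph == (0, 0) and pw == (0, 0):
        return x
    return np.pad(x, ((0, 0), ph, pw, (0, 0)), constant_values=fill)


def im2col(xp: np.ndarray, k: int, stride: int, ho: int, wo: int) -> np.ndarray:
    """Gather k*k patches from padded NHWC input.

    Returns an array of shape (B, ho, wo, k*k*C); a plain loop over the k*k
    offsets keeps memory traffic linear and avoids scatter/gather indexing.
    """
    b, _, _, c = xp.shape
    cols = np.empty((b, ho, wo, k * k, c), dtype=xp.dtype)
    for ki in range(k):
        for kj in range(k):
            cols[:, :, :, ki * k + kj, :] = xp[
                :, ki : ki + ho * stride : stride, kj : kj + wo * stride : stride, :
            ]
    return cols.reshape(b, ho, wo, k * k * c)


def col2im(
    dcols: np.ndarray,
    xp_shape: tuple[int, ...],
    k: int,
    stride: int,
    ho: int,
    wo: int,
) -> np.ndarray:
    """Scatter-add patch gradients back onto the padded input."""
    b, hp, wp, c = xp_shape
    dxp = np.zeros((b, hp, wp, c), dtype=dcols.dtype)
    d = dcols.reshape(b, ho, wo, k * k, c)
    for ki in range(k):
        for kj in range(k):
            dxp[
                :, ki : ki + ho * stride : stride, kj : kj + wo * stride : stride, :
            ] += d[:, :, :, ki * k + kj, :]
    return dxp


def unpad(dxp: np.ndarray, orig_h: int, orig_w: int, k: int, stride: int) -> np.ndarray:
    ph0, _ = same_pad_amount(orig_h, k, stride)
    pw0, _ = same_pad_amount(orig_w, k, stride)
    return dxp[:, ph0 : ph0 + orig_h, pw0 : pw0 + orig_w, :]
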
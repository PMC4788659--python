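"""Differential LBP (DLBP): difference thresholding against the window std.

A neighbor's bit is set only when its gray-level difference from the
center exceeds the standard deviation of the whole ``(2R+1) x (2R+1)``
window (center included, population form):

    bit_p = 0  if |g_p - g_c| <= sigma,   else 1
    code  = sum_p bit_p * 2^(p-1)

Compared with plain LBP this suppresses bits raised by speckle-scale
fluctuations and keeps only salient local edges, so a spatially regular
texture maps to a flat code image while granular, nodular texture keeps
structure.

All comparisons are done in exact integer arithmetic: with ``n`` window
pixels, sum ``S`` and sum of squares ``S2``,

    |d| > sigma  <=>  n * (n - ddof) * d**2 > n * S2 - S**2

so the scalar and vectorized paths agree bit-for-bit and no floating-point
rounding can flip a bit at the ``|d| = sigma`` boundary.
"""

from __future__ import annotations

import numpy as np

from hepatex.image_io import validate_template
from hepatex.lbp import NeighborhoodConfig, make_neighborhood, _check_window


def dlbp_code(
    window: np.ndarray,
    config: NeighborhoodConfig,
    *,
    absolute_difference: bool = True,
    ddof: int = 0,
) -> int:
    """DLBP code of the center pixel of one full window.

    Parameters
    ----------
    window
        Square gray-level window of side ``2R + 1``.
    config
        Neighbor ring from :func:`hepatex.lbp.make_neighborhood`.
    absolute_difference
        Compare ``|g_p - g_c|`` against sigma (default).  With ``False``
        the signed difference is used, so all neighbors darker than the
        center give bit 0 regardless of magnitude.
    ddof
        Delta degrees of freedom of the window standard deviation:
        0 = population (default), 1 = sample.
    """
    arr = _check_window(window, config)
    r = config.radius
    n = arr.size
    s = int(arr.sum())
    s2 = int((arr.astype(np.int64) ** 2).sum())
    var_num = n * s2 - s * s  # = n^2 * population variance
    center = int(arr[r, r])
    code = 0
    for p, (dr, dc) in enumerate(config.offsets):
        d = int(arr[r + dr, r + dc]) - center
        if absolute_difference:
            d = abs(d)
        elif d < 0:
            continue
        if n * (n - ddof) * d * d > var_num:
            code |= 1 << p
    return code


def dlbp_image(
    template: np.ndarray,
    radius: int,
    *,
    absolute_difference: bool = True,
    ddof: int = 0,
) -> np.ndarray:
    """Apply the DLBP operator over every interior pixel of a template.

    Returns an ``int64`` code image of shape ``(H - 2R, W - 2R)``; same
    valid-region contract as :func:`hepatex.lbp.lbp_image`.
    """
    arr = validate_template(template)
    config = make_neighborhood(radius)
    r = config.radius
    h, w = arr.shape
    side = 2 * r + 1
    if h < side or w < side:
        raise ValueError(
            f"template {h}x{w} too small for radius {r} (needs >= {side})"
        )
    n = side * side

    # Exact windowed sums via integral images (int64 throughout).
    def window_sum(values: np.ndarray) -> np.ndarray:
        ii = np.zeros((h + 1, w + 1), dtype=np.int64)
        np.cumsum(np.cumsum(values, axis=0), axis=1, out=ii[1:, 1:])
        return (
            ii[side:, side:] - ii[:-side, side:] - ii[side:, :-side]
            + ii[:-side, :-side]
        )

    s = window_sum(arr)
    s2 = window_sum(arr * arr)
    var_num = n * s2 - s * s  # n^2 * population variance per window

    center = arr[r : h - r, r : w - r]
    codes = np.zeros_like(center, dtype=np.int64)
    scale = n * (n - ddof)
    for p, (dr, dc) in enumerate(config.offsets):
        d = arr[r + dr : h - r + dr, r + dc : w - r + dc] - center
        if absolute_difference:
            d = np.abs(d)
        else:
            d = np.where(d < 0, 0, d)  # signed: darker neighbors never exceed
        bit = scale * d * d > var_num
        if not absolute_difference:
            bit &= d > 0
        codes |= bit.astype(np.int64) << p
    return codes
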
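"""Otsu threshold selection, binarization and complement.

The threshold ``t*`` maximizes the between-class variance of the gray-level
histogram,

    sigma_B^2(t) = w0 (mu0 - muT)^2 + w1 (mu1 - muT)^2,

where class C0 collects levels ``<= t`` and C1 the levels above.  Candidate
thresholds with an empty class are excluded; ties go to the smallest ``t``.

LBP-family code images are first min-max rescaled to the 8-bit range
``[0, 255]`` (raw code ranges grow as ``2^(8R)``, so a fixed 256-bin
histogram keeps thresholds comparable across radii).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

GRAY_LEVELS = 256


class DegenerateHistogramError(ValueError):
    """Raised when only a single gray level is occupied (no two-class split)."""


@dataclass(frozen=True)
class OtsuResult:
    """Optimal threshold and the class statistics at that threshold."""

    threshold: int
    between_class_variance: float
    omega0: float
    omega1: float
    mu0: float
    mu1: float
    mu_total: float


def histogram(image: np.ndarray, levels: int = GRAY_LEVELS) -> np.ndarray:
    """Gray-level counts ``n_i`` for ``i`` in ``[0, levels-1]``.

    Raises
    ------
    ValueError
        If any value falls outside ``[0, levels - 1]``.
    """
    arr = np.asarray(image)
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(f"histogram requires integer values, got {arr.dtype}")
    flat = arr.ravel()
    if flat.size == 0:
        raise ValueError("cannot histogram an empty image")
    if flat.min() < 0 or flat.max() >= levels:
        raise ValueError(f"values outside [0, {levels - 1}]")
    return np.bincount(flat, minlength=levels).astype(np.int64)


def otsu_threshold(counts: np.ndarray) -> OtsuResult:
    """Between-class-variance-maximizing threshold of a histogram.

    Evaluates ``sigma_B^2(t)`` at every ``t`` with both classes nonempty
    and returns the smallest maximizing ``t``.  Values within 1e-10
    relative of the maximum count as ties: unoccupied gray-level stretches
    make sigma_B^2 mathematically constant across many ``t``, and rounding
    noise must not pick an arbitrary member of such a plateau.

    Raises
    ------
    DegenerateHistogramError
        If fewer than two gray levels are occupied.
    """
    counts = np.asarray(counts, dtype=np.float64)
    if counts.ndim != 1:
        raise ValueError("histogram must be 1-D")
    total = counts.sum()
    if total <= 0:
        raise DegenerateHistogramError("empty histogram")
    if np.count_nonzero(counts) < 2:
        raise DegenerateHistogramError(
            "single occupied gray level; no two-class threshold exists"
        )
    levels = counts.size
    p = counts / total
    i = np.arange(levels, dtype=np.float64)
    omega = np.cumsum(p)  # omega(t) for t = 0..L-1
    mu = np.cumsum(i * p)  # mu(t)
    mu_total = mu[-1]

    # Candidates t = 0..L-2 with omega0 in (0, 1).
    omega0 = omega[:-1]
    mu0_cum = mu[:-1]
    valid = (omega0 > 0) & (omega0 < 1)
    sigma_b = np.full(levels - 1, -np.inf)
    w0 = omega0[valid]
    w1 = 1.0 - w0
    m0 = mu0_cum[valid] / w0
    m1 = (mu_total - mu0_cum[valid]) / w1
    sigma_b[valid] = w0 * (m0 - mu_total) ** 2 + w1 * (m1 - mu_total) ** 2

    best = sigma_b.max()
    tol = 1e-10 * max(best, 1e-30)
    t_star = int(np.flatnonzero(sigma_b >= best - tol)[0])  # smallest tie
    w0s = float(omega0[t_star])
    w1s = 1.0 - w0s
    m0s = float(mu0_cum[t_star] / w0s)
    m1s = float((mu_total - mu0_cum[t_star]) / w1s)
    return OtsuResult(
        threshold=t_star,
        between_class_variance=float(sigma_b[t_star]),
        omega0=w0s,
        omega1=w1s,
        mu0=m0s,
        mu1=m1s,
        mu_total=float(mu_total),
    )


def binarize(image: np.ndarray, result: OtsuResult | int) -> np.ndarray:
    """Threshold an image: 0 (black, class C0) where ``value <= t*``, else 1."""
    t = result.threshold if isinstance(result, OtsuResult) else int(result)
    arr = np.asarray(image)
    return (arr > t).astype(np.uint8)


def complement(image: np.ndarray) -> np.ndarray:
    """Flip every bit of a {0,1} binary image."""
    arr = np.asarray(image)
    if arr.size and not np.isin(arr, (0, 1)).all():
        raise ValueError("complement expects a {0,1} binary image")
    return (1 - arr).astype(np.uint8)


def rescale_codes(codes: np.ndarray, levels: int = GRAY_LEVELS) -> np.ndarray:
    """Min-max rescale a code image to integer levels ``[0, levels-1]``.

    ``level = floor((levels-1) * (code - min) / (max - min))``.

    Raises
    ------
    DegenerateHistogramError
        If the code image is constant (no spread to rescale).
    """
    arr = np.asarray(codes)
    lo = int(arr.min())
    hi = int(arr.max())
    if hi == lo:
        raise DegenerateHistogramError("constant code image cannot be rescaled")
    span = hi - lo
    scaled = ((levels - 1) * (arr.astype(np.int64) - lo)) // span
    return scaled.astype(np.int64)
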
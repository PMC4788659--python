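"""Local binary pattern (LBP) transform on square neighborhood rings.

The code of a pixel compares each of the P neighbors on the perimeter of
the ``(2R+1) x (2R+1)`` window against the center gray value:

    code = sum_{p=1..P} s(g_p - g_c) * 2^(p-1),   s(z) = 1 if z >= 0 else 0

so the code lies in ``[0, 2^P - 1]`` with ``P = 8R`` (8, 16, 24 neighbors
for radii 1, 2, 3; window sizes 3x3, 5x5, 7x7).  Neighbors are taken on the
square perimeter without sub-pixel interpolation, ordered starting due east
``(0, +R)`` and proceeding counterclockwise (rows pointing up).  Borders
are not padded: the output shrinks by ``2R`` per axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from hepatex.image_io import validate_template


@dataclass(frozen=True)
class NeighborhoodConfig:
    """Sampling ring: radius and the ordered neighbor offsets.

    ``offsets[p]`` is the ``(row, col)`` displacement of neighbor ``p+1``
    relative to the center pixel.
    """

    radius: int
    offsets: tuple[tuple[int, int], ...]

    @property
    def neighbor_count(self) -> int:
        return len(self.offsets)

    @property
    def window_side(self) -> int:
        return 2 * self.radius + 1


@lru_cache(maxsize=None)
def make_neighborhood(radius: int) -> NeighborhoodConfig:
    """Build the square-perimeter ring for a given radius.

    The ring walks the perimeter of the ``(2R+1)``-sided window starting at
    ``(0, +R)`` (due east) and turning counterclockwise: up the east edge,
    west along the top edge, down the west edge, east along the bottom edge,
    and back up to just below the start.  All ``8R`` perimeter cells appear
    exactly once and the center is excluded.
    """
    if radius < 1:
        raise ValueError(f"radius must be >= 1, got {radius}")
    r = radius
    offsets: list[tuple[int, int]] = []
    # East edge going up: (0,R) .. (-R,R)
    offsets += [(-dr, r) for dr in range(0, r + 1)]
    # Top edge going west: (-R,R-1) .. (-R,-R)
    offsets += [(-r, dc) for dc in range(r - 1, -r - 1, -1)]
    # West edge going down: (-R+1,-R) .. (R,-R)
    offsets += [(dr, -r) for dr in range(-r + 1, r + 1)]
    # Bottom edge going east: (R,-R+1) .. (R,R)
    offsets += [(r, dc) for dc in range(-r + 1, r + 1)]
    # East edge below start: (R-1,R) .. (1,R)
    offsets += [(dr, r) for dr in range(r - 1, 0, -1)]
    assert len(offsets) == 8 * r and len(set(offsets)) == 8 * r
    return NeighborhoodConfig(radius=r, offsets=tuple(offsets))


def _check_window(window: np.ndarray, config: NeighborhoodConfig) -> np.ndarray:
    arr = validate_template(window)
    side = config.window_side
    if arr.shape != (side, side):
        raise ValueError(
            f"window must be {side}x{side} for radius {config.radius}, "
            f"got shape {arr.shape}"
        )
    return arr


def lbp_code(window: np.ndarray, config: NeighborhoodConfig) -> int:
    """LBP code of the center pixel of one full window."""
    arr = _check_window(window, config)
    r = config.radius
    center = arr[r, r]
    code = 0
    for p, (dr, dc) in enumerate(config.offsets):
        if arr[r + dr, r + dc] >= center:
            code |= 1 << p
    return code


def lbp_image(template: np.ndarray, radius: int) -> np.ndarray:
    """Apply the LBP operator over every interior pixel of a template.

    Returns an ``int64`` code image of shape ``(H - 2R, W - 2R)``.
    """
    arr = validate_template(template)
    config = make_neighborhood(radius)
    r = config.radius
    h, w = arr.shape
    if h < 2 * r + 1 or w < 2 * r + 1:
        raise ValueError(
            f"template {h}x{w} too small for radius {r} (needs >= {2 * r + 1})"
        )
    center = arr[r : h - r, r : w - r]
    codes = np.zeros_like(center, dtype=np.int64)
    for p, (dr, dc) in enumerate(config.offsets):
        neighbor = arr[r + dr : h - r + dr, r + dc : w - r + dc]
        codes |= (neighbor >= center).astype(np.int64) << p
    return codes
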
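"""Synthetic test textures: regular periodic and irregular nodular patches.

The irregular generator emulates the micronodular look of cirrhotic
parenchyma at ROI scale: a mid-gray background, additive zero-mean
Gaussian speckle, and dark overlapping discs standing in for the
millet-seed-sized regenerating nodules (1-2.5 mm, a few pixels at typical
B-mode resolution).  The regular generator produces a two-tone periodic
tiling, the idealized analog of homogeneous normal parenchyma.

These are code-path exercisers, not B-mode simulations: no point-spread
function, attenuation, or multiplicative Rayleigh speckle (a
multiplicative option is available via ``multiplicative_speckle``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

BACKGROUND_LEVEL = 128
REGULAR_TONES = (100, 180)


@dataclass(frozen=True)
class TextureSpec:
    """Parameters of one synthetic template.

    ``kind`` is ``"regular"`` (periodic two-tone tiling, deterministic) or
    ``"irregular"`` (speckled background with dark granular blobs, seeded).
    ``period`` is the full spatial period of the regular tiling in pixels
    (even, >= 2; each tone band is ``period // 2`` wide).  Blob radii are
    drawn uniformly from ``blob_radius_range`` (pixels) and centers
    uniformly over the image; ``blob_contrast`` is the gray-level
    darkening, ``speckle_std`` the speckle standard deviation in gray
    levels.
    """

    kind: str
    size: int = 50
    period: int = 2
    pattern: str = "checker"  # or "stripes"
    blob_count: int = 12
    blob_radius_range: tuple[float, float] = (2.0, 4.0)
    blob_contrast: int = 80
    speckle_std: float = 10.0
    multiplicative_speckle: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size < 7:
            raise ValueError(f"size must be >= 7, got {self.size}")
        if self.kind not in ("regular", "irregular"):
            raise ValueError(f"unknown texture kind {self.kind!r}")
        if self.kind == "regular":
            if self.period < 2 or self.period % 2:
                raise ValueError(f"period must be even and >= 2, got {self.period}")
            if self.pattern not in ("checker", "stripes"):
                raise ValueError(f"unknown pattern {self.pattern!r}")
        else:
            if self.blob_radius_range[0] < 1:
                raise ValueError("minimum blob radius must be >= 1")
            if self.blob_radius_range[0] > self.blob_radius_range[1]:
                raise ValueError("blob_radius_range must be (min, max)")
            if self.speckle_std < 0:
                raise ValueError("speckle_std must be >= 0")
            if self.blob_count < 0:
                raise ValueError("blob_count must be >= 0")


def generate_regular(spec: TextureSpec) -> np.ndarray:
    """Deterministic two-tone periodic tiling (checker or stripes)."""
    if spec.kind != "regular":
        raise ValueError("spec.kind must be 'regular'")
    cell = spec.period // 2
    r = np.arange(spec.size) // cell
    c = np.arange(spec.size) // cell
    if spec.pattern == "checker":
        parity = (r[:, None] + c[None, :]) % 2
    else:
        parity = np.broadcast_to(c[None, :] % 2, (spec.size, spec.size))
    lo, hi = REGULAR_TONES
    return np.where(parity == 0, lo, hi).astype(np.uint8)


def generate_irregular(spec: TextureSpec) -> np.ndarray:
    """Seeded nodular texture: speckled background plus dark discs."""
    if spec.kind != "irregular":
        raise ValueError("spec.kind must be 'irregular'")
    rng = np.random.default_rng(spec.seed)
    img = np.full((spec.size, spec.size), float(BACKGROUND_LEVEL))
    if spec.speckle_std > 0:
        noise = rng.normal(0.0, spec.speckle_std, size=img.shape)
        if spec.multiplicative_speckle:
            img *= 1.0 + noise / BACKGROUND_LEVEL
        else:
            img += noise
    rows, cols = np.mgrid[0 : spec.size, 0 : spec.size]
    rmin, rmax = spec.blob_radius_range
    for _ in range(spec.blob_count):
        cy = rng.uniform(0, spec.size)
        cx = rng.uniform(0, spec.size)
        radius = rng.uniform(rmin, rmax)
        mask = (rows - cy) ** 2 + (cols - cx) ** 2 <= radius**2
        img[mask] -= spec.blob_contrast
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def generate(spec: TextureSpec) -> np.ndarray:
    """Dispatch on ``spec.kind``."""
    if spec.kind == "regular":
        return generate_regular(spec)
    return generate_irregular(spec)


def generate_dataset(
    n_per_class: int, seed: int = 0, size: int = 50
) -> tuple[list[np.ndarray], list[str]]:
    """Paired regular/irregular templates with per-template derived seeds.

    Labels follow the study convention: regular -> ``normal``,
    irregular -> ``cirrhotic``.
    """
    templates: list[np.ndarray] = []
    labels: list[str] = []
    for i in range(n_per_class):
        templates.append(
            generate_regular(TextureSpec(kind="regular", size=size))
        )
        labels.append("normal")
        templates.append(
            generate_irregular(
                TextureSpec(kind="irregular", size=size, seed=(seed * 100003 + i) % (2**31))
            )
        )
        labels.append("cirrhotic")
    return templates, labels
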
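"""Grayscale image reading and square ROI extraction.

Templates are plain 2-D ``numpy`` arrays of integer gray levels in
``[0, L-1]`` with ``L = 256`` for 8-bit input.  Coordinates are 0-based and
row-major; a template window is the half-open block
``[top, top+size) x [left, left+size)``.
"""

from __future__ import annotations

import os

import numpy as np
from PIL import Image, UnidentifiedImageError

GRAY_LEVELS = 256


def read_gray_image(path: str | os.PathLike) -> np.ndarray:
    """Read an image file as an 8-bit grayscale array.

    Color inputs are converted to luminance with the Rec. 601 weights
    (Pillow mode ``"L"``), rounded to the nearest integer.

    Parameters
    ----------
    path
        PNG, JPEG or TIFF file (8-bit grayscale or RGB).

    Returns
    -------
    numpy.ndarray
        2-D ``uint8`` array of shape ``(height, width)``.

    Raises
    ------
    IOError
        If the file does not exist or cannot be decoded as an image.
    """
    try:
        with Image.open(path) as img:
            gray = img.convert("L")
            return np.asarray(gray, dtype=np.uint8)
    except (FileNotFoundError, UnidentifiedImageError, OSError) as exc:
        raise IOError(f"cannot read image file {os.fspath(path)!r}: {exc}") from exc


def extract_template(
    image: np.ndarray, top: int, left: int, size: int
) -> np.ndarray:
    """Copy a ``size x size`` window out of ``image``.

    Raises
    ------
    ValueError
        If the requested window does not lie fully inside the image.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {image.shape}")
    if size < 1:
        raise ValueError(f"template size must be >= 1, got {size}")
    height, width = image.shape
    if top < 0 or left < 0 or top + size > height or left + size > width:
        raise ValueError(
            f"template window [{top}:{top + size}, {left}:{left + size}] "
            f"exceeds image bounds {height}x{width}"
        )
    return image[top : top + size, left : left + size].copy()


def write_gray_png(path: str | os.PathLike, image: np.ndarray) -> None:
    """Write a 2-D integer array as an 8-bit grayscale PNG.

    Binary {0,1} images are expanded to {0,255} so they are visible;
    anything else must already fit ``uint8``.
    """
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {arr.shape}")
    if arr.size and arr.max() <= 1:
        arr = (arr * 255).astype(np.uint8)
    else:
        if arr.min() < 0 or arr.max() > 255:
            raise ValueError("pixel values outside [0, 255]; rescale before writing")
        arr = arr.astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path, format="PNG")


def validate_template(image: np.ndarray, levels: int = GRAY_LEVELS) -> np.ndarray:
    """Check a template's dtype and value range, returning it as ``int64``."""
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D template, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(f"template must hold integer gray levels, got {arr.dtype}")
    if arr.size and (arr.min() < 0 or arr.max() >= levels):
        raise ValueError(f"gray levels outside [0, {levels - 1}]")
    return arr.astype(np.int64)
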